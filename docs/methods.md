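# Methods

This note documents the models and procedures the package implements,
the parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Scope and assumptions

The package operates downstream of structure sampling: pose ensembles
arrive as PDB files sharing one receptor coordinate frame (the output
convention of ligand-binding refinement protocols that keep the
receptor fixed in space). No structural superposition is performed; if
ensembles from different runs are combined, aligning them first is the
caller's responsibility. Residue identity is `(chain, residue number)`;
insertion codes are rejected rather than silently mangled. Docking
scores and dose-response measurements are consumed as input — neither
docking nor assay modelling is reimplemented.

## Pose clustering

RMSD is computed on the ligand atoms plus all atoms of receptor
residues having any heavy atom within `pocket_radius` (default 4.0 Å)
of the ligand in *any* pose, excluding non-polar hydrogens. Using the
union over poses fixes one atom set for the whole ensemble, which makes
the pairwise RMSD a true metric; since the receptor frame is shared,
the receptor atoms contribute no variance but keep the normalization
comparable to pipelines where they move.

Average linkage (UPGMA on distances) is implemented directly with an
O(N³) Lance–Williams update so ties are broken deterministically by
the smallest pair of cluster representative indices. The scipy
implementation serves as an independent cross-check in the tests, not
as the implementation.

The cut level is the smallest k with R²(k) ≥ `r2_threshold` (default
0.7), where R² = 1 − SSW/SST on **squared** pairwise distances (SSW per
cluster is Σ d²/(2 n_c)). Whether dispersion should be measured on
distances or squared distances is genuinely open; squared distances are
the ANOVA-like convention and are used here, flagged in the
configuration. "Strain" is reported as the ratio of the linkage height
of the merge that produced the k-cluster partition to the height of the
merge before it — ≥ 1 for a monotone linkage, close to 1 when the
dendrogram is smooth around the cut — defined as 1.0 at the boundaries
(k = N, N−1) and when both heights are zero. Representatives are
medoids (minimal summed intra-cluster distance, ties to the lowest pose
index).

A two-stage protocol of cluster → manual inspection → re-cluster is
replaced here by cluster → compatibility filter → optional re-cluster,
because visual inspection is not implementable; the mutagenesis filter
is the operative criterion anyway.

## Interaction detection

All detectors work on heavy-atom geometry; cutoffs are configurable
(`InteractionConfig`) with defaults:

| kind        | criterion                                      | default |
|-------------|------------------------------------------------|---------|
| hbond       | N/O/S donor–acceptor distance                  | ≤ 3.5 Å, D–H···A ≥ 120° when an H is attached |
| salt bridge | oppositely charged heavy atoms                 | ≤ 4.0 Å |
| π–π         | ring centroid distance; interplanar angle      | ≤ 5.5 Å; ≤ 30° (face) or 60–90° (edge) |
| cation–π    | charged N to ring centroid (either direction)  | ≤ 6.0 Å |
| hydrophobic | side-chain C/S to ligand C/S, inclusive        | ≤ 5.0 Å |

The hydrophobic default is anchored to the field convention that a
4.7 Å carbon–carbon separation still counts as a contact while 5.3 Å
counts as distant. Structures without hydrogens are accepted; H-bond
detection then degrades to the distance criterion alone, and the record
notes it. Tyrosine ring carbons are treated as hydrophobic-capable
(the hydroxyl stays out of the hydrophobic atom set); whether Tyr
should count for apolar contacts at all is ambiguous, and the choice is
deliberately permissive.

Ligand connectivity is inferred from covalent radii (+0.45 Å tolerance)
when CONECT records are absent; rings are planar 5/6-cycles of the
smallest cycle basis. Formal charges come from the PDB charge column or
an annotation; failing both, aliphatic nitrogens with ≤ 3 heavy
neighbours are treated as protonated (a pH-7 heuristic for amines).
Multiple detected kinds per (pose, residue) cell are kept as a set;
"interacting" means the set is non-empty.

## Dose-response fitting and classification

The four-parameter Hill equation is fitted on log10 concentration by
`scipy.optimize.least_squares` from a multistart grid (6 log-spaced
EC50 starts over the observed range × Hill coefficients {0.5, 1, 2}),
parametrized as (f_min, amplitude ≥ 0, log10 EC50, n) with bounds
n ∈ [0.1, 10] and EC50 within two decades of the observed range.
Standard errors come from the Jacobian at the optimum. A series whose
observed range is below `noise_floor` (default 0.1 ΔF/F) is flagged
no-response and fitted flat instead of raising. Replicates are averaged
per concentration before fitting.

The involvement rule compares *fitted maximal responses* (amplitude is
the stated criterion; the fitted f_max is the robust estimate of it,
with the top-concentration mean as fallback when the fit fails):
not involved when mutant ≥ wild type, involved when wild type − mutant
≥ `delta_threshold` (default 0.1 ΔF/F, deliberately approximate),
ambiguous between. Severity: abolished (no-response flag), retained
residual (involved but the top-concentration response still reaches
25% of the wild-type maximum), reduced, wild-type-like, enhanced
(exceeds wild type by ≥ the threshold). Pure EC50 shifts with preserved
amplitude are recorded in the notes and flip the class only when the
opt-in `use_ec50_shift` criterion is enabled (ratio ≥ 10 by default) —
amplitude, not potency, is the primary decision axis.

## Compatibility selection

Agreement per non-ambiguous residue: involved ⇔ interacting cell.
Enhanced phenotypes are treated like wild-type-like ones — the residue
must show *no* favorable contact in a compatible pose, which is what an
improvement upon removing the side chain implies. Any interaction kind
(including hydrophobic-only) satisfies an involved residue. Scores are
agreement fractions over non-ambiguous residues; ranking breaks ties by
H-bond/salt-bridge agreement count and then input order. An
all-ambiguous phenotype makes every pose score 1.0 vacuously and the
report flags non-informativeness. The second workflow cycle (other
agonists on the validated conformation) is the same operation on a new
ensemble and phenotype; no separate code path exists.

## Analogue screening

Environment fingerprints follow the MOLPRINT-2D idea with an
approximated atom typing: element + aromaticity flag + heavy-neighbour
count, shells at bond distances 1..2 (radius configurable). The exact
typing scheme and radius of the original descriptor are not asserted
as equivalent — this is documented as an approximation. Similarity is
the Tanimoto coefficient on environment-string sets (both-empty defined
as 0, with a warning). The selection rule "score similar or better than
the parent" is operationalized as score ≤ parent + `score_tolerance`
with tolerance 0.0 by default; "similar" is vague, so the tolerance is
exposed.

## Synthetic generators

`gen_pose_ensemble` builds a geometric toy pocket: idealized side-chain
fragments of the 8-residue panel (K86, F89, N93, F181, L185, Y244,
N247, L251) on a 12 Å circle facing a central ligand site — the
topology of an orthosteric pocket between transmembrane helices, not a
folded protein. Ligand poses are assembled from per-residue probe
groups planted at canonical geometries (H-bond 2.9 Å, salt bridge
3.2 Å, hydrophobic 3.8 Å, parallel π-stack 3.8 Å, cation–π 4.5 Å);
inactive probes are parked near the pocket axis ≥ 12 Å from every
residue anchor. Pose-group centres sit on a lateral circle (radius
capped at 5 Å, axial steps beyond) so that every pair of groups is
separated by the requested displacement without perturbing planted
contacts.

Within-group jitter is a per-pose **rigid translation** whose norm is
capped at 0.55 Å — just below the tightest planted margin (H-bond:
2.9 Å planted vs 3.5 Å cutoff). Consequences, by design: planted
patterns survive detection at any jitter sd (plant-then-detect closure
is exact by construction), internal ligand geometry (ring planarity,
H-bond angles) is never distorted, and the jitter sd controls cluster
scatter up to the cap. What this generator does **not** emulate:
receptor flexibility, conformational ligand changes, correlated noise,
or near-degenerate binding modes — so passing tests demonstrate the
correctness of the detection/clustering/selection machinery, not
robustness to real structural noise.

`gen_dose_response` adds Gaussian noise (default sd 0.02 ΔF/F, a
realistic plate-reader scale) to Hill curves over 8 half-log
concentrations (0.1–300 µM, 3 replicates) and clips at zero; the noise
model is homoscedastic, which real calcium-mobilization data is not.
The packaged quinine-like panel plants the canonical phenotype split;
the wild-type-like construct is planted at 1.06× the wild-type
amplitude because an exactly equal amplitude would make the strict
"mutant ≥ wild type" rule a coin flip under noise — "similar or
slightly improved" is the phenotype being modelled.

`gen_analogue_set` mutates up to two terminal heavy atoms of the parent
graph and verifies the planted similarity class by direct fingerprint
computation; dissimilar molecules come from a fixed scaffold list. All
generators are bit-reproducible under their seed and record it in the
output metadata.

## Problem sizes and numerics

Default study sizes — ensembles of ~20 poses in 3 groups for partition
recovery, 100 poses for fingerprint closure, 100 series for EC50
recovery, 7 representatives for selection — were chosen so each
property is measured with comfortable statistics while any single stage
runs in seconds. Degenerate inputs are defined rather than crashed:
R² = 1 when total dispersion is zero, strain = 1 at dendrogram
boundaries, Tanimoto = 0 for two empty sets, single-pose ensembles
cluster trivially, flat dose-response series return flagged flat fits.

## Known limitations

* No symmetry-corrected ligand RMSD; chemically equivalent atom
  permutations inflate distances.
* Halogen bonds, water bridges and metal coordination are out of scope.
* The hydrophobic detector counts all ligand carbons, including polar-
  adjacent ones.
* The Hill fit assumes independent homoscedastic errors; no outlier
  handling or plate normalization.
* Compatibility scoring is combinatorial, not probabilistic — it cannot
  weigh partial agreement by effect size.
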