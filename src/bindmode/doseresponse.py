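"""Hill dose-response fitting and residue-involvement classification.

Calcium-mobilization responses (ΔF/F) of receptor constructs are fitted
with the four-parameter Hill equation

    F(c) = f_min + (f_max − f_min) · cⁿ / (EC50ⁿ + cⁿ)

by multistart nonlinear least squares on log10 concentration.  A mutated
residue is classified from the comparison of the mutant's fitted maximal
response with the wild type's: *not involved* when the mutant responds as
strongly as (or stronger than) the wild type, *involved* when the maximal
response drops by at least ``delta_threshold`` (default 0.1 ΔF/F), and
*ambiguous* in between.  Severity distinguishes abolished, reduced and
retained-residual responses, plus wild-type-like and enhanced phenotypes.

EC50 shifts with preserved amplitude are recorded in the notes but do not
flip the class unless ``use_ec50_shift`` is enabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DataError

__all__ = [
    "hill",
    "HillFit",
    "HillModel",
    "HillResults",
    "PhenotypeEntry",
    "PhenotypeVector",
    "classify_involvement",
    "phenotype_vector",
]

CLASSES = ("involved", "not_involved", "ambiguous")
SEVERITIES = (
    "abolished", "reduced", "retained_residual", "wild_type_like", "enhanced"
)


def hill(
    conc: np.ndarray, f_min: float, f_max: float, ec50: float, n: float
) -> np.ndarray:
    """Hill equation; ``conc`` and ``ec50`` in µM."""
    c = np.asarray(conc, dtype=float)
    return f_min + (f_max - f_min) / (1.0 + (ec50 / c) ** n)


@dataclass
class HillFit:
    """Fitted Hill parameters with fit diagnostics."""

    f_min: float
    f_max: float
    ec50: float
    hill_n: float
    rss: float
    converged: bool
    no_response: bool = False
    se: dict = field(default_factory=dict)

    @property
    def amplitude(self) -> float:
        return self.f_max - self.f_min

    @property
    def max_response(self) -> float:
        """Maximal response used by the involvement rule (fitted f_max)."""
        return self.f_max


class HillModel:
    """Hill dose-response model for one (construct, ligand) series.

    Parameters
    ----------
    conc_uM, response
        Paired concentration (µM, positive) and ΔF/F arrays.  Replicates
        at the same concentration may be passed as repeated rows or
        pre-averaged via :meth:`from_table`.
    """

    #: EC50 multistart grid size (log-spaced over the observed range).
    N_EC50_STARTS = 6
    #: Hill-coefficient start values.
    N_STARTS = (0.5, 1.0, 2.0)

    def __init__(self, conc_uM, response):
        c = np.asarray(conc_uM, dtype=float)
        y = np.asarray(response, dtype=float)
        if c.shape != y.shape or c.ndim != 1:
            raise DataError("conc_uM and response must be equal-length 1-D")
        if np.any(c <= 0):
            raise DataError("concentrations must be positive")
        order = np.argsort(c)
        self.conc = c[order]
        self.response = y[order]
        if len(np.unique(self.conc)) < 4:
            raise DataError(
                "need >= 4 distinct concentrations to fit a Hill curve"
            )

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        construct: str,
        ligand: str | None = None,
        average_replicates: bool = True,
    ) -> "HillModel":
        """Build a model from a dose-response table for one construct."""
        sub = table[table["construct"] == construct]
        if ligand is not None:
            sub = sub[sub["ligand"] == ligand]
        if sub.empty:
            raise DataError(
                f"no rows for construct {construct!r}"
                + (f", ligand {ligand!r}" if ligand else "")
            )
        if average_replicates:
            sub = (
                sub.groupby("conc_uM", as_index=False)["dFF"]
                .mean()
                .sort_values("conc_uM")
            )
        return cls(sub["conc_uM"].to_numpy(), sub["dFF"].to_numpy())

    def _fit_once(self, p0, bounds):
        logc = np.log10(self.conc)

        def residual(p):
            f_min, amp, log_ec50, n = p
            pred = f_min + amp / (1.0 + 10 ** (n * (log_ec50 - logc)))
            return pred - self.response

        return least_squares(residual, p0, bounds=bounds, method="trf")

    def fit(self, noise_floor: float = 0.1) -> "HillResults":
        """Multistart least-squares fit.

        A series whose observed range falls below ``noise_floor`` (ΔF/F)
        is flagged as no-response and fitted as a flat line rather than
        raising.
        """
        y = self.response
        y_range = float(np.max(y) - np.min(y))
        if y_range < noise_floor:
            level = float(np.mean(y))
            fit = HillFit(
                f_min=level,
                f_max=level,
                ec50=float(np.median(self.conc)),
                hill_n=1.0,
                rss=float(np.sum((y - level) ** 2)),
                converged=True,
                no_response=True,
            )
            return HillResults(self, fit)

        logc = np.log10(self.conc)
        lo = [
            float(np.min(y) - 2 * y_range), 0.0, float(logc.min() - 2.0), 0.1,
        ]
        hi = [
            float(np.max(y) + 2 * y_range),
            4 * y_range,
            float(logc.max() + 2.0),
            10.0,
        ]
        ec50_grid = np.linspace(logc.min(), logc.max(), self.N_EC50_STARTS)
        best = None
        for log_ec50 in ec50_grid:
            for n0 in self.N_STARTS:
                p0 = [float(np.min(y)), y_range, float(log_ec50), n0]
                p0 = np.clip(p0, lo, hi)
                try:
                    res = self._fit_once(p0, (lo, hi))
                except Exception:
                    continue
                if best is None or res.cost < best.cost:
                    best = res
        if best is None:
            raise DataError("Hill fit failed from every start")
        f_min, amp, log_ec50, n = best.x
        at_bound = bool(
            np.any(np.isclose(best.x[2:], np.array(lo)[2:], atol=1e-6))
            or np.any(np.isclose(best.x[2:], np.array(hi)[2:], atol=1e-6))
        )
        rss = float(2 * best.cost)
        se = {}
        try:
            _, s, vt = np.linalg.svd(best.jac, full_matrices=False)
            keep = s > np.finfo(float).eps * max(best.jac.shape) * s[0]
            cov = (vt[keep].T / s[keep] ** 2) @ vt[keep]
            dof = max(len(y) - 4, 1)
            sig = np.sqrt(np.diag(cov) * rss / dof)
            se = {
                "f_min": float(sig[0]),
                "f_max": float(np.hypot(sig[0], sig[1])),
                "log10_ec50": float(sig[2]),
                "hill_n": float(sig[3]),
            }
        except np.linalg.LinAlgError:
            pass
        fit = HillFit(
            f_min=float(f_min),
            f_max=float(f_min + amp),
            ec50=float(10 ** log_ec50),
            hill_n=float(n),
            rss=rss,
            converged=bool(best.success and not at_bound),
            no_response=False,
            se=se,
        )
        return HillResults(self, fit)


@dataclass
class HillResults:
    """Fitted Hill curve with prediction, summary and plotting."""

    model: HillModel
    fit: HillFit

    @property
    def params(self) -> dict:
        f = self.fit
        return {
            "f_min": f.f_min,
            "f_max": f.f_max,
            "ec50_uM": f.ec50,
            "hill_n": f.hill_n,
        }

    def predict(self, conc_uM) -> np.ndarray:
        f = self.fit
        return hill(conc_uM, f.f_min, f.f_max, f.ec50, f.hill_n)

    def summary(self) -> str:
        f = self.fit
        lines = [
            "Hill dose-response fit",
            f"  f_min   {f.f_min:9.4f} ΔF/F",
            f"  f_max   {f.f_max:9.4f} ΔF/F"
            + (
                f"   (se {f.se['f_max']:.4f})" if "f_max" in f.se else ""
            ),
            f"  EC50    {f.ec50:9.4g} µM",
            f"  n_Hill  {f.hill_n:9.3f}",
            f"  RSS     {f.rss:9.5f}   converged: {f.converged}"
            + ("   NO RESPONSE" if f.no_response else ""),
        ]
        return "\n".join(lines)

    def plot(self, ax=None, label: str | None = None):
        """Data points and fitted curve on a log concentration axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        ax.semilogx(m.conc, m.response, "o", label=label)
        grid = np.logspace(
            np.log10(m.conc.min()) - 0.5, np.log10(m.conc.max()) + 0.5, 200
        )
        ax.semilogx(grid, self.predict(grid), "-")
        ax.set_xlabel("concentration (µM)")
        ax.set_ylabel("ΔF/F")
        return ax


@dataclass
class PhenotypeEntry:
    """Involvement call for one mutated residue."""

    residue_key: tuple
    construct: str
    class_: str
    severity: str
    effect_size: float  # mutant max response − wild-type max response
    notes: str = ""

    def __post_init__(self):
        if self.class_ not in CLASSES:
            raise ValueError(f"unknown class {self.class_!r}")
        if self.severity not in SEVERITIES:
            raise ValueError(f"unknown severity {self.severity!r}")
        involved_sev = self.severity in (
            "abolished", "reduced", "retained_residual"
        )
        if (self.class_ == "not_involved") == involved_sev:
            raise ValueError(
                f"{self.construct}: class {self.class_!r} inconsistent with "
                f"severity {self.severity!r}"
            )


@dataclass
class PhenotypeVector:
    """Per-residue involvement classes for one ligand."""

    ligand: str
    wt_construct: str
    entries: dict = field(default_factory=dict)  # residue_key -> entry
    wt_fit: HillFit | None = None
    fits: dict = field(default_factory=dict)  # construct -> HillFit

    @property
    def residue_keys(self) -> list[tuple]:
        return list(self.entries)

    def class_of(self, key: tuple) -> str:
        return self.entries[tuple(key)].class_

    @property
    def involved(self) -> list[tuple]:
        return [k for k, e in self.entries.items() if e.class_ == "involved"]

    @property
    def not_involved(self) -> list[tuple]:
        return [
            k for k, e in self.entries.items() if e.class_ == "not_involved"
        ]

    @property
    def ambiguous(self) -> list[tuple]:
        return [k for k, e in self.entries.items() if e.class_ == "ambiguous"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, e in self.entries.items():
            fit = self.fits.get(e.construct)
            rows.append(
                {
                    "residue": f"{key[0]}{key[1]}",
                    "construct": e.construct,
                    "class": e.class_,
                    "severity": e.severity,
                    "effect_size": e.effect_size,
                    "f_max": fit.f_max if fit else np.nan,
                    "ec50_uM": fit.ec50 if fit else np.nan,
                    "notes": e.notes,
                }
            )
        return pd.DataFrame(rows)


def _top_concentration_response(series_fit: HillFit, model: HillModel) -> float:
    top = model.conc.max()
    return float(np.mean(model.response[model.conc == top]))


def classify_involvement(
    wt_fit: HillFit,
    mut_fit: HillFit,
    delta_threshold: float = 0.1,
    residue_key: tuple = ("A", 0),
    construct: str = "",
    mut_model: HillModel | None = None,
    residual_fraction: float = 0.25,
    use_ec50_shift: bool = False,
    ec50_shift_factor: float = 10.0,
) -> PhenotypeEntry:
    """Classify one residue from wild-type and mutant Hill fits.

    A residue is *not involved* when the mutant maximal response is at
    least the wild type's; *involved* when it is lower by at least
    ``delta_threshold`` ΔF/F; *ambiguous* between.  Severity: abolished
    (mutant flagged no-response), retained_residual (involved but the
    mutant still reaches ``residual_fraction`` of the wild-type maximum
    at the top concentrations), reduced (other involved), enhanced
    (mutant exceeds wild type by >= ``delta_threshold``), wild_type_like.
    """
    if wt_fit is None:
        raise DataError("wild-type fit is required")
    wt_max = wt_fit.max_response
    mut_max = mut_fit.max_response
    delta = wt_max - mut_max
    notes = []
    if (
        not mut_fit.no_response
        and not wt_fit.no_response
        and mut_fit.ec50 > 0
        and wt_fit.ec50 > 0
    ):
        ratio = mut_fit.ec50 / wt_fit.ec50
        if ratio >= ec50_shift_factor or ratio <= 1.0 / ec50_shift_factor:
            notes.append(f"EC50 shift x{ratio:.2g}")

    if mut_max >= wt_max:
        class_ = "not_involved"
        severity = (
            "enhanced" if mut_max - wt_max >= delta_threshold
            else "wild_type_like"
        )
    elif delta >= delta_threshold:
        class_ = "involved"
        if mut_fit.no_response:
            severity = "abolished"
        else:
            if mut_model is not None:
                top = _top_concentration_response(mut_fit, mut_model)
            else:
                top = mut_max
            if top >= residual_fraction * wt_max:
                severity = "retained_residual"
            else:
                severity = "reduced"
    else:
        # reduced, but by less than the decision threshold: no hard call
        class_ = "ambiguous"
        severity = "reduced"
        notes.append(f"reduction {delta:.3f} below threshold")

    if use_ec50_shift and class_ != "involved" and not mut_fit.no_response:
        ratio = mut_fit.ec50 / max(wt_fit.ec50, 1e-12)
        if ratio >= ec50_shift_factor:
            class_ = "involved"
            severity = "reduced"
            notes.append("classified involved by EC50-shift criterion")

    return PhenotypeEntry(
        residue_key=tuple(residue_key),
        construct=construct,
        class_=class_,
        severity=severity,
        effect_size=float(mut_max - wt_max),
        notes="; ".join(notes),
    )


def phenotype_vector(
    table: pd.DataFrame,
    ligand: str,
    wt_construct: str,
    residue_map: dict,
    delta_threshold: float = 0.1,
    noise_floor: float = 0.1,
    use_ec50_shift: bool = False,
) -> PhenotypeVector:
    """Fit every construct for one ligand and classify each mutated residue.

    ``residue_map`` maps mutant construct ids to residue keys
    ``(chain, number)`` (or bare numbers, stored as ("A", number)).
    Replicates are averaged per concentration before fitting.
    """
    constructs = sorted(
        table.loc[table["ligand"] == ligand, "construct"].unique()
    )
    if wt_construct not in constructs:
        raise DataError(
            f"wild-type construct {wt_construct!r} absent for ligand "
            f"{ligand!r}"
        )
    mutants = [c for c in constructs if c != wt_construct]
    unmapped = [c for c in mutants if c not in residue_map]
    if unmapped:
        raise DataError(f"unmapped construct(s): {unmapped}")

    wt_model = HillModel.from_table(table, wt_construct, ligand)
    wt_fit = wt_model.fit(noise_floor=noise_floor).fit
    vector = PhenotypeVector(ligand=ligand, wt_construct=wt_construct)
    vector.wt_fit = wt_fit
    vector.fits[wt_construct] = wt_fit
    for construct in mutants:
        key = residue_map[construct]
        if isinstance(key, int):
            key = ("A", key)
        mut_model = HillModel.from_table(table, construct, ligand)
        mut_fit = mut_model.fit(noise_floor=noise_floor).fit
        entry = classify_involvement(
            wt_fit,
            mut_fit,
            delta_threshold=delta_threshold,
            residue_key=tuple(key),
            construct=construct,
            mut_model=mut_model,
            use_ec50_shift=use_ec50_shift,
        )
        vector.entries[tuple(key)] = entry
        vector.fits[construct] = mut_fit
    return vector
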