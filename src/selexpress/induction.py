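"""Induction summaries and Hill dose-response fitting.

Reporter fluorescence is normalized per cell density, fold induction is the
ratio of induced to uninduced normalized fluorescence (medians first for
population data), and dose series are fit to the Hill equation

    y(L) = y0 + Vmax * L^n / (Km^n + L^n)

by bounded nonlinear least squares with a multi-start grid over (Km, n).
Vmax is the maximal induced activity above basal, Km the ligand
concentration at half-maximal response (sensitivity) and n the Hill
coefficient (cooperativity).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


# ---------------------------------------------------------------------------
# normalization and ratios


def normalize(gfp_raw, od600, blank_gfp: float = 0.0, blank_od: float = 0.0):
    """Blank-subtracted fluorescence per blank-subtracted OD600."""
    gfp = np.asarray(gfp_raw, dtype=float)
    od = np.asarray(od600, dtype=float)
    if np.any(od <= blank_od):
        raise ValueError("od600 must exceed the blank OD for normalization")
    return (gfp - blank_gfp) / (od - blank_od)


def _median_if_population(x) -> float:
    arr = np.asarray(x, dtype=float)
    return float(np.median(arr)) if arr.size > 1 else float(arr.reshape(()))


def fold_induction(norm_induced, norm_uninduced) -> float:
    """Induced / uninduced normalized fluorescence (medians for populations)."""
    num = _median_if_population(norm_induced)
    den = _median_if_population(norm_uninduced)
    if den == 0:
        raise ZeroDivisionError("uninduced fluorescence is zero")
    return num / den


def fold_repression(norm_no_atf, norm_with_atf) -> float:
    """No-repressor / repressed normalized fluorescence (medians first)."""
    num = _median_if_population(norm_no_atf)
    den = _median_if_population(norm_with_atf)
    if den == 0:
        raise ZeroDivisionError("repressed fluorescence is zero")
    return num / den


def summarize_induction(
    records: pd.DataFrame,
    blank_gfp: float = 0.0,
    blank_od: float = 0.0,
    reference_clone: str | None = None,
) -> pd.DataFrame:
    """Per-clone induction summary from ExpressionRecord rows.

    Expects columns clone_id, condition (uninduced/induced), od600, gfp_raw.
    Returns norm_uninduced, norm_induced, fold_induction and, when a
    reference clone is named, percent_of_constitutive relative to that
    clone's uninduced activity.
    """
    required = {"clone_id", "condition", "od600", "gfp_raw"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for clone, grp in records.groupby("clone_id", sort=False):
        vals = {}
        for cond in ("uninduced", "induced"):
            sub = grp[grp["condition"] == cond]
            if len(sub) == 0:
                raise ValueError(f"clone {clone}: no {cond} measurements")
            vals[cond] = _median_if_population(
                normalize(sub["gfp_raw"], sub["od600"], blank_gfp, blank_od)
            )
        rows.append((clone, vals["uninduced"], vals["induced"],
                     vals["induced"] / vals["uninduced"]))
    out = pd.DataFrame(
        rows, columns=["clone_id", "norm_uninduced", "norm_induced", "fold_induction"]
    )
    if reference_clone is not None:
        ref = out.loc[out["clone_id"] == reference_clone, "norm_uninduced"]
        if len(ref) == 0:
            raise ValueError(
                f"reference clone {reference_clone!r} absent; cannot compute "
                "percent of constitutive activity"
            )
        out["percent_of_constitutive"] = 100.0 * out["norm_uninduced"] / float(ref.iloc[0])
    return out


# ---------------------------------------------------------------------------
# Hill model


def hill_curve(L, y0, vmax, km, n):
    L = np.asarray(L, dtype=float)
    with np.errstate(invalid="ignore"):
        frac = np.where(L > 0, L**n / (km**n + L**n), 0.0)
    return y0 + vmax * frac


@dataclass
class HillResults:
    """Fitted Hill parameters with uncertainties and diagnostics."""

    y0: float
    vmax: float
    km: float
    hill_n: float
    bse: dict
    residual_sse: float
    converged: bool
    n_obs: int
    n_starts_converged: int
    model: "HillModel"

    @property
    def params(self) -> dict:
        return {"y0": self.y0, "vmax": self.vmax, "km": self.km, "hill_n": self.hill_n}

    @property
    def non_inducible(self) -> bool:
        """Flat response: fitted dynamic range below 2% of the data scale."""
        scale = float(np.max(np.abs(self.model.response))) or 1.0
        return self.vmax < 0.02 * scale

    def predict(self, ligand_conc):
        return hill_curve(ligand_conc, self.y0, self.vmax, self.km, self.hill_n)

    def summary(self) -> str:
        lines = [
            "Hill dose-response fit",
            "=" * 40,
            f"observations: {self.n_obs}   converged: {self.converged}"
            + ("   [non-inducible]" if self.non_inducible else ""),
            f"{'param':>8} {'estimate':>12} {'std err':>10}",
        ]
        for k, v in self.params.items():
            se = self.bse.get(k, float("nan"))
            lines.append(f"{k:>8} {v:>12.4g} {se:>10.3g}")
        lines.append(f"residual SSE: {self.residual_sse:.6g}")
        return "\n".join(lines)

    def plot(self, ax=None):  # pragma: no cover - plotting convenience
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogx(self.model.ligand_conc + self.model._log_offset, self.model.response, "o",
                    label="data")
        grid = np.geomspace(
            max(self.model._log_offset, 1e-3), self.model.ligand_conc.max() * 1.5, 200
        )
        ax.semilogx(grid, self.predict(grid), "-", label="Hill fit")
        ax.set_xlabel("ligand (uM)")
        ax.set_ylabel("normalized fluorescence")
        ax.legend()
        return ax


class HillModel:
    """Nonlinear Hill regression of a dose series.

    Parameters
    ----------
    ligand_conc, response : array-like
        Paired observations; replicates appear as repeated concentrations.
        At least 4 distinct concentrations including 0 are required.
    fix_y0 : float or None
        Constrain the basal level (e.g. 0 after background subtraction);
        default leaves y0 free.
    """

    N_BOUNDS = (1e-3, 10.0)

    def __init__(self, ligand_conc, response, fix_y0: float | None = None):
        self.ligand_conc = np.asarray(ligand_conc, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if self.ligand_conc.shape != self.response.shape:
            raise ValueError("ligand_conc and response must align")
        distinct = np.unique(self.ligand_conc)
        if len(distinct) < 4 or 0.0 not in distinct:
            raise ValueError("need >= 4 distinct concentrations including 0")
        if (self.response <= 0).any():
            raise ValueError("responses must be positive fluorescence values")
        self.fix_y0 = fix_y0
        pos = distinct[distinct > 0]
        self._log_offset = float(pos.min()) / 10.0

    def fit(self, km_starts: int = 5, n_starts=(0.5, 1.0, 2.0, 4.0)) -> HillResults:
        L, y = self.ligand_conc, self.response
        pos = np.unique(L[L > 0])
        km_grid = np.geomspace(pos.min(), pos.max(), km_starts)
        y0_start = float(np.min(y))
        vmax_start = max(float(np.max(y) - np.min(y)), 1e-6 * float(np.max(y)))

        if self.fix_y0 is None:
            def f(Lx, y0, vmax, km, n):
                return hill_curve(Lx, y0, vmax, km, n)
            lower = [0.0, 0.0, 1e-12, self.N_BOUNDS[0]]
            upper = [np.inf, np.inf, np.inf, self.N_BOUNDS[1]]
            make_p0 = lambda km, n: [y0_start, vmax_start, km, n]
        else:
            y0_fixed = float(self.fix_y0)

            def f(Lx, vmax, km, n):
                return hill_curve(Lx, y0_fixed, vmax, km, n)
            lower = [0.0, 1e-12, self.N_BOUNDS[0]]
            upper = [np.inf, np.inf, self.N_BOUNDS[1]]
            make_p0 = lambda km, n: [vmax_start, km, n]

        best = None
        n_ok = 0
        for km0 in km_grid:
            for n0 in n_starts:
                try:
                    popt, pcov = curve_fit(
                        f, L, y, p0=make_p0(km0, n0), bounds=(lower, upper),
                        maxfev=20000,
                    )
                except (RuntimeError, ValueError):
                    continue
                sse = float(((y - f(L, *popt)) ** 2).sum())
                n_ok += 1
                if best is None or sse < best[0]:
                    best = (sse, popt, pcov)
        if best is None:
            nan = float("nan")
            return HillResults(nan, nan, nan, nan, {}, nan, False, len(y), 0, self)
        sse, popt, pcov = best
        with np.errstate(invalid="ignore"):
            perr = np.sqrt(np.diag(pcov))
        if self.fix_y0 is None:
            y0, vmax, km, n = popt
            bse = dict(zip(("y0", "vmax", "km", "hill_n"), perr))
        else:
            vmax, km, n = popt
            y0 = float(self.fix_y0)
            bse = dict(zip(("vmax", "km", "hill_n"), perr))
            bse["y0"] = 0.0
        return HillResults(
            float(y0), float(vmax), float(km), float(n), bse, sse, True, len(y),
            n_ok, self,
        )


def fit_hill(ligand_conc, response, fix_y0: float | None = None) -> HillResults:
    """Convenience wrapper: HillModel(...).fit()."""
    return HillModel(ligand_conc, response, fix_y0=fix_y0).fit()


# ---------------------------------------------------------------------------
# sequence-diversity ("speedometer") coordinates


def levenshtein(a: str, b: str) -> int:
    """Edit distance (substitutions, insertions, deletions)."""
    if a == b:
        return 0
    return int(edlib.align(a, b, mode="NW", task="distance")["editDistance"])


def speedometer_coordinates(
    sequences, fold_inductions, reference: str | None = None
) -> pd.DataFrame:
    """Radial edit distance to a reference vs angular fold induction.

    The reference defaults to the operator with the highest fold induction
    (plotted at the center of the diversity wheel).
    """
    seqs = list(sequences)
    fis = np.asarray(fold_inductions, dtype=float)
    if len(seqs) != len(fis):
        raise ValueError("sequences and fold_inductions must align")
    if reference is None:
        reference = seqs[int(np.argmax(fis))]
    dist = [levenshtein(s, reference) for s in seqs]
    return pd.DataFrame(
        {"sequence": seqs, "radial": dist, "angular": fis, "reference": reference}
    )


__all__ = [
    "HillModel",
    "HillResults",
    "fit_hill",
    "fold_induction",
    "fold_repression",
    "hill_curve",
    "levenshtein",
    "normalize",
    "speedometer_coordinates",
    "summarize_induction",
]
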