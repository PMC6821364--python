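"""Seed selection and enrichment-weighted position weight matrices.

The most enriched gapped k-mer seeds the motif; enrichments of every
1-mismatch variant of the seed weight the PWM columns.  Spacer (wildcard)
positions carry no selection information and are emitted as flagged uniform
columns.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kmers import (
    BASES,
    GappedKmer,
    MarkovBackground,
    expected_count,
)

DNA = "ACGT"


class DegenerateSeedError(ValueError):
    """All variants of a seed position failed the count filter."""


@dataclass
class PositionWeightMatrix:
    """Per-position probability columns over an alphabet.

    ``wildcard_mask[i]`` marks spacer positions whose columns are uniform
    placeholders rather than measured preferences.
    """

    probs: np.ndarray  # (length, |alphabet|)
    alphabet: str = DNA
    wildcard_mask: np.ndarray | None = None
    source_seed: GappedKmer | None = None

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != len(self.alphabet):
            raise ValueError("probs must be (length, |alphabet|)")
        if self.wildcard_mask is None:
            self.wildcard_mask = np.zeros(len(self.probs), dtype=bool)
        self.wildcard_mask = np.asarray(self.wildcard_mask, dtype=bool)
        if (self.probs < -1e-12).any():
            raise ValueError("probabilities must be non-negative")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("every PWM column must sum to 1")

    def __len__(self) -> int:
        return len(self.probs)

    @property
    def info_content(self) -> np.ndarray:
        """Per-position information content in bits (log2 |alphabet| - H)."""
        p = np.clip(self.probs, 1e-300, 1.0)
        H = -(self.probs * np.log2(p)).sum(axis=1)
        return np.log2(len(self.alphabet)) - H

    @property
    def consensus(self) -> str:
        out = []
        for i, row in enumerate(self.probs):
            out.append("x" if self.wildcard_mask[i] else self.alphabet[int(np.argmax(row))])
        return "".join(out)

    def column_correlations(self, other: "PositionWeightMatrix | np.ndarray") -> np.ndarray:
        """Pearson correlation of matching columns (non-wildcard only)."""
        o = other.probs if isinstance(other, PositionWeightMatrix) else np.asarray(other)
        if o.shape != self.probs.shape:
            raise ValueError("shape mismatch")
        out = []
        for i in range(len(self.probs)):
            if self.wildcard_mask[i]:
                out.append(np.nan)
                continue
            a, b = self.probs[i], o[i]
            with np.errstate(invalid="ignore"):
                out.append(float(np.corrcoef(a, b)[0, 1]))
        return np.asarray(out)


def select_seed(table: pd.DataFrame) -> GappedKmer:
    """Most enriched pattern; ties broken by observed count, then text."""
    if table is None or len(table) == 0:
        raise ValueError("enrichment table is empty")
    best = table.sort_values(
        ["enrichment", "observed", "pattern"], ascending=[False, False, True]
    ).iloc[0]
    return GappedKmer.from_text(best["pattern"])


def mismatch_enrichments(
    seed: GappedKmer,
    sample_counts: Mapping[str, int],
    model: MarkovBackground,
    length_counts: Mapping[int, float],
    count_threshold: int = 50,
    convention: str = "single-position",
) -> np.ndarray:
    """Enrichment of every 1-mismatch variant of the seed.

    Returns a (span, 4) array; wildcard rows are NaN.  The seed base keeps
    the seed's own enrichment; variants absent from the sample or failing
    the count filter get 0.
    """
    text = seed.text
    span = seed.span
    out = np.full((span, 4), np.nan)

    def enr(pattern_text: str) -> float:
        obs = sample_counts.get(pattern_text, 0)
        if obs < count_threshold:
            return 0.0
        exp = expected_count(
            model, GappedKmer.from_text(pattern_text), length_counts, convention
        )
        return obs / exp if exp > 0 else 0.0

    for i, c in enumerate(text):
        if c == "x":
            continue
        for j, b in enumerate(BASES):
            variant = text[:i] + b + text[i + 1 :]
            out[i, j] = enr(variant)
    return out


def build_pwm(
    mismatch_matrix: np.ndarray,
    seed: GappedKmer | None = None,
    weight_transform: str = "linear",
) -> PositionWeightMatrix:
    """Normalize per-position enrichment weights into PWM columns.

    ``linear`` (default) uses the enrichment values directly; ``log`` uses
    log1p(enrichment), compressing the dynamic range.  Wildcard (NaN) rows
    become flagged uniform columns.  A non-wildcard position where every
    variant failed the count filter is degenerate and raises.
    """
    m = np.asarray(mismatch_matrix, dtype=np.float64)
    wildcard = np.all(np.isnan(m), axis=1)
    if weight_transform == "log":
        w = np.log1p(np.where(np.isnan(m), 0.0, m))
    elif weight_transform == "linear":
        w = np.where(np.isnan(m), 0.0, m)
    else:
        raise ValueError(f"unknown weight_transform {weight_transform!r}")
    probs = np.empty_like(w)
    for i in range(len(w)):
        if wildcard[i]:
            probs[i] = 0.25
            continue
        tot = w[i].sum()
        if tot <= 0:
            raise DegenerateSeedError(f"all variants at position {i} below count filter")
        probs[i] = w[i] / tot
    return PositionWeightMatrix(
        probs, alphabet=DNA, wildcard_mask=wildcard, source_seed=seed
    )


# ---------------------------------------------------------------------------
# logo rendering (local; no external service)

_LOGO_COLORS = {
    "A": "#109648", "C": "#255c99", "G": "#f7b32b", "T": "#d62839", "-": "#777777"
}


def plot_logo(pwm: PositionWeightMatrix, ax=None, bits: bool = True):
    """Stacked-letter sequence logo drawn with matplotlib text paths.

    Letter heights are probability * information content when ``bits`` is
    true (the conventional bits logo), plain probabilities otherwise.
    Wildcard columns render greyed.
    """
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    if ax is None:
        _, ax = plt.subplots(figsize=(0.6 * len(pwm) + 1, 2.2))
    fp = FontProperties(family="DejaVu Sans", weight="bold")
    ic = pwm.info_content if bits else np.ones(len(pwm))
    for i in range(len(pwm)):
        heights = pwm.probs[i] * ic[i]
        order = np.argsort(heights)
        y = 0.0
        for j in order:
            h = heights[j]
            if h <= 1e-3:
                continue
            ch = pwm.alphabet[j]
            tp = TextPath((0, 0), ch, size=1.0, prop=fp)
            bb = tp.get_extents()
            scale_x = 0.9 / bb.width
            scale_y = h / bb.height
            tr = (
                Affine2D()
                .translate(-bb.x0, -bb.y0)
                .scale(scale_x, scale_y)
                .translate(i + 0.05, y)
            )
            color = "#aaaaaa" if pwm.wildcard_mask[i] else _LOGO_COLORS.get(ch, "black")
            ax.add_patch(PathPatch(tp.transformed(tr), facecolor=color, edgecolor="none"))
            y += h
    ax.set_xlim(0, len(pwm))
    ax.set_ylim(0, np.log2(len(pwm.alphabet)) if bits else 1.0)
    ax.set_xticks(np.arange(len(pwm)) + 0.5)
    ax.set_xticklabels(np.arange(1, len(pwm) + 1))
    ax.set_ylabel("bits" if bits else "probability")
    return ax


__all__ = [
    "DegenerateSeedError",
    "PositionWeightMatrix",
    "build_pwm",
    "mismatch_enrichments",
    "plot_logo",
    "select_seed",
]
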