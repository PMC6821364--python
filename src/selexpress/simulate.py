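"""Synthetic SELEX and expression data with the structure the pipeline assumes.

Three generators mirror the study design end to end:

* a compositionally biased randomized library of 16-19 bp spacers drawn from
  an order-5 Markov chain,
* iterative affinity selection against a planted palindromic dimeric motif
  (Boltzmann reweighting at inverse-temperature-like stringency beta,
  followed by multinomial re-amplification each round),
* repressor-occupancy-driven reporter expression: an allosteric
  transcription factor (aTF) occupies its operator with occupancy
  theta = R_eff / (R_eff + Kd), the effective free repressor falling with
  ligand as R_eff = atf_level / (1 + L / ligand_kd); expression is
  v_const * (1 - theta) with multiplicative lognormal noise, which yields
  Hill-shaped dose responses without ever fitting one in.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kmers import BASES, MarkovBackground, _CODE

#: Stationary base composition of the default biased library (A, C, G, T).
#: Strongly unequal per-base delivery, as seen in randomized oligo pools with
#: skewed phosphoramidite mixing.  The composition is complement-balanced in
#: the sense that each complement pair has one common member (A with T), so
#: palindromic dimeric operators remain reachable by selection, and skewed
#: enough that the census of gapped k-mers passing the 50-count filter at
#: 10^5-read sequencing depth sits well above the filter (the regime the
#: null-enrichment calibration band presumes).
DEFAULT_BASE_FREQS = (0.60, 0.04, 0.03, 0.33)

#: Milder composition used for affinity-selection scenarios.  Motif
#: recovery needs the starting library to contain tens of perfect planted
#: sites and no ultra-rare letters (a "private" rare spacer letter in a
#: single selected read would otherwise carry more enrichment leverage than
#: the planted consensus itself).
SELECTION_BASE_FREQS = (0.32, 0.18, 0.12, 0.38)

DEFAULT_LIBRARY_LENGTHS = (16, 17, 18, 19)


# ---------------------------------------------------------------------------
# background models


def uniform_background(order: int = 5) -> MarkovBackground:
    S = 4**order
    cond = np.full((S, 4), 0.25)
    init = np.full(S, 1.0 / S)
    return MarkovBackground(cond, init, order=order)


def biased_background(
    base_freqs=DEFAULT_BASE_FREQS, persistence: float = 0.10, order: int = 5
) -> MarkovBackground:
    """Order-``order`` chain with unequal base frequencies and a mild
    preference (``persistence``) for repeating the previous base.

    The stationary state distribution is computed by power iteration so the
    model is exactly self-consistent.
    """
    freqs = np.asarray(base_freqs, dtype=np.float64)
    if freqs.shape != (4,) or not np.isclose(freqs.sum(), 1.0):
        raise ValueError("base_freqs must be 4 probabilities summing to 1")
    S = 4**order
    states = np.arange(S)
    last = states & 3
    cond = np.tile(freqs, (S, 1))
    cond[states, last] *= 1.0 + persistence
    cond /= cond.sum(axis=1, keepdims=True)
    # stationary distribution of the state chain by power iteration
    init = np.full(S, 1.0 / S)
    suffix = states % (S // 4)
    for _ in range(200):
        new = np.zeros(S)
        for b in range(4):
            np.add.at(new, suffix * 4 + b, init * cond[:, b])
        if np.abs(new - init).sum() < 1e-14:
            init = new
            break
        init = new
    return MarkovBackground(cond, init / init.sum(), order=order)


def sample_reads(
    model: MarkovBackground, length: int, n_reads: int, rng: np.random.Generator
) -> list[str]:
    """Vectorized draw of ``n_reads`` sequences of one length from the chain."""
    if length < model.order:
        raise ValueError("read length below model order")
    S = 4 ** model.order
    out = np.empty((n_reads, length), dtype=np.int64)
    state = rng.choice(S, size=n_reads, p=model.initial)
    for t in range(model.order - 1, -1, -1):
        out[:, model.order - 1 - t] = (state >> (2 * t)) & 3
    cum = np.cumsum(model.conditional, axis=1)
    for pos in range(model.order, length):
        u = rng.random(n_reads)
        b = (u[:, None] > cum[state]).sum(axis=1)
        out[:, pos] = b
        state = (state % (S // 4)) * 4 + b
    lut = np.frombuffer("".join(BASES).encode(), dtype=np.uint8)
    chars = lut[out]
    joined = chars.tobytes().decode("ascii")
    return [joined[i * length : (i + 1) * length] for i in range(n_reads)]


def generate_background_library(
    background: MarkovBackground,
    lengths=DEFAULT_LIBRARY_LENGTHS,
    n_reads: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Equimolar (+-1 read) mix of the requested lengths from the chain."""
    lengths = tuple(lengths)
    if not lengths:
        raise ValueError("lengths set must be non-empty")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per = [n_reads // len(lengths)] * len(lengths)
    for i in range(n_reads - sum(per)):
        per[i] += 1
    reads: list[str] = []
    for L, n in zip(lengths, per):
        if n:
            reads.extend(sample_reads(background, L, n, rng))
    return reads


# ---------------------------------------------------------------------------
# planted motif + selection


@dataclass(frozen=True)
class PlantedMotif:
    """Dimeric operator motif: two half-site PWMs separated by a fixed spacer.

    Binding energy of a window is the additive log-odds score
    ``sum -ln(p_col[base] / 0.25)``; the energy of a sequence is the minimum
    over all offsets (best site wins).
    """

    left_pwm: np.ndarray  # (w_left, 4) column-normalized probabilities
    right_pwm: np.ndarray
    spacer: int
    #: optional weak preference over the spacer positions (spacer, 4); the
    #: spacer never reaches a consensus, but dimeric repressors mildly favor
    #: A/T tracts (narrow minor groove) between the half sites
    spacer_pwm: np.ndarray | None = None

    def __post_init__(self):
        pwms = [self.left_pwm, self.right_pwm]
        if self.spacer_pwm is not None:
            if np.shape(self.spacer_pwm) != (self.spacer, 4):
                raise ValueError("spacer_pwm must be (spacer, 4)")
            pwms.append(self.spacer_pwm)
        for p in pwms:
            if not np.allclose(np.asarray(p).sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("motif PWM columns must sum to 1")

    @property
    def span(self) -> int:
        return len(self.left_pwm) + self.spacer + len(self.right_pwm)

    @property
    def consensus(self) -> tuple[str, str]:
        cl = "".join(BASES[i] for i in np.argmax(self.left_pwm, axis=1))
        cr = "".join(BASES[i] for i in np.argmax(self.right_pwm, axis=1))
        return cl, cr

    @property
    def core_pattern(self) -> str:
        cl, cr = self.consensus
        return cl + "x" * self.spacer + cr

    def _weights(self) -> np.ndarray:
        mid = (
            np.full((self.spacer, 4), 0.0)
            if self.spacer_pwm is None
            else -np.log(np.asarray(self.spacer_pwm) / 0.25)
        )
        return np.vstack(
            [
                -np.log(np.asarray(self.left_pwm) / 0.25),
                mid,
                -np.log(np.asarray(self.right_pwm) / 0.25),
            ]
        )

    def energies(self, seqs: list[str]) -> np.ndarray:
        """Minimum-over-offsets energy for each sequence."""
        w = self._weights()
        informative = np.ptp(w, axis=1) > 0
        out = np.empty(len(seqs))
        # batch per length, preserving per-sequence order
        by_len: dict[int, list[int]] = {}
        for i, s in enumerate(seqs):
            by_len.setdefault(len(s), []).append(i)
        for L, idx in by_len.items():
            if L < self.span:
                out[idx] = np.inf
                continue
            batch = np.array(
                [[_CODE[c] for c in seqs[i].upper()] for i in idx], dtype=np.int64
            )
            noff = L - self.span + 1
            escore = np.full((len(idx), noff), 0.0)
            for j in range(self.span):
                if not informative[j]:
                    continue
                cols = batch[:, j : j + noff]
                escore += w[j][cols]
            out[idx] = escore.min(axis=1)
        return out


def default_planted_motif(consensus_prob: float = 0.8) -> PlantedMotif:
    """Palindromic AACAA .. spacer-3 .. TTGTT dimeric site.

    The two half sites are reverse complements (the dimeric-repressor
    signature); the central C/G pair sits on the rare side of the library
    composition while the A/T positions are common, so perfect sites are
    present in a deep starting library yet strongly enriched over it.
    """

    def pwm(consensus: str) -> np.ndarray:
        p = np.full((len(consensus), 4), (1.0 - consensus_prob) / 3.0)
        for i, c in enumerate(consensus):
            p[i, _CODE[c]] = consensus_prob
        return p

    return PlantedMotif(pwm("AACAA"), pwm("TTGTT"), spacer=3)


@dataclass
class SelectionSimConfig:
    """Conditions of the in vitro selection emulation (defaults follow the
    study design: five rounds, four pooled spacer lengths)."""

    true_motif: PlantedMotif = field(default_factory=default_planted_motif)
    library_lengths: tuple = DEFAULT_LIBRARY_LENGTHS
    reads_per_round: int = 50_000
    rounds: int = 5
    stringency: float = 2.0  # beta
    background: MarkovBackground | None = None
    seed: int = 0

    def __post_init__(self):
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.reads_per_round < 1:
            raise ValueError("reads_per_round must be >= 1")
        if self.stringency < 0:
            raise ValueError("stringency beta must be >= 0")


def selection_weights(pool: Counter, motif: PlantedMotif, beta: float) -> np.ndarray:
    """Normalized per-unique-sequence sampling probabilities for one round."""
    seqs = list(pool)
    cnts = np.array([pool[s] for s in seqs], dtype=np.float64)
    if beta == 0:
        return cnts / cnts.sum()
    E = motif.energies(seqs)
    E = np.where(np.isfinite(E), E, E[np.isfinite(E)].max(initial=0.0) + 50.0)
    logw = -beta * (E - E.min())
    w = cnts * np.exp(logw)
    return w / w.sum()


def simulate_selection(
    library, config: SelectionSimConfig
) -> list[Counter]:
    """Per-round read pools (sequence -> count), rounds 1..config.rounds.

    Each round draws ``reads_per_round`` reads from the previous pool with
    probability proportional to ``count * exp(-beta * E)`` (affinity capture
    plus PCR re-amplification modelled as one multinomial draw).
    """
    rng = np.random.default_rng(config.seed)
    pool = library if isinstance(library, Counter) else Counter(library)
    if not pool:
        raise ValueError("library must be non-empty")
    rounds: list[Counter] = []
    for _ in range(config.rounds):
        seqs = list(pool)
        p = selection_weights(pool, config.true_motif, config.stringency)
        draw = rng.multinomial(config.reads_per_round, p)
        pool = Counter(
            {s: int(c) for s, c in zip(seqs, draw) if c > 0}
        )
        rounds.append(pool)
    return rounds


# ---------------------------------------------------------------------------
# expression / dose response


@dataclass
class ExpressionSimConfig:
    """Occupancy-model expression simulation.

    Concentrations: operator Kd and atf_level in nM, ligand_kd in uM
    (matching the dose axis); v_const in arbitrary fluorescence/OD units.
    """

    atf_level: float = 100.0  # nM effective free repressor, no ligand
    ligand_kd: float = 10.0  # uM
    v_const: float = 100.0
    noise_cv: float = 0.05
    od600: float = 0.5
    #: fraction of DNA-binding activity the ligand-bound repressor retains;
    #: > 0 gives finite induction plateaus (residual binding at saturation),
    #: 0 recovers the fully-releasable limit where expression -> v_const.
    residual_activity: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.atf_level, self.ligand_kd, self.v_const) <= 0:
            raise ValueError("concentrations and v_const must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def occupancy(
    kd: float,
    atf_level: float,
    ligand_conc,
    ligand_kd: float,
    residual_activity: float = 0.0,
):
    """Repressor occupancy theta(L) of the operator (closed form).

    The effective DNA-binding repressor pool is the apo fraction plus
    ``residual_activity`` times the holo (ligand-bound) fraction:
    ``R_eff = atf * (1 + w*L/ligand_kd) / (1 + L/ligand_kd)``.
    """
    L = np.asarray(ligand_conc, dtype=float)
    x = L / ligand_kd
    r_eff = atf_level * (1.0 + residual_activity * x) / (1.0 + x)
    return r_eff / (r_eff + kd)


def expected_expression(kd: float, ligand_conc, config: ExpressionSimConfig):
    """Noise-free expression v_const * (1 - theta)."""
    theta = occupancy(
        kd, config.atf_level, ligand_conc, config.ligand_kd,
        config.residual_activity,
    )
    return config.v_const * (1.0 - theta)


def simulate_expression(
    operator_kds: dict[str, float],
    ligand_concs,
    config: ExpressionSimConfig,
    replicates: int = 1,
) -> pd.DataFrame:
    """ExpressionRecord rows for a dose series of each operator clone.

    Columns: clone_id, condition, ligand_conc (uM), od600, gfp_raw.
    Fluorescence carries multiplicative lognormal noise with the configured
    CV (mean-corrected, so the expectation equals the closed form).
    """
    ligand_concs = np.asarray(ligand_concs, dtype=float)
    if (ligand_concs < 0).any():
        raise ValueError("ligand concentrations must be >= 0")
    rng = np.random.default_rng(config.seed)
    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))
    rows = []
    for clone, kd in operator_kds.items():
        if kd <= 0:
            raise ValueError("operator Kd must be > 0")
        mean = expected_expression(kd, ligand_concs, config)
        for _ in range(replicates):
            if sigma > 0:
                noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=mean.shape))
            else:
                noise = np.ones_like(mean)
            expr = mean * noise
            for L, y in zip(ligand_concs, expr):
                rows.append(
                    (
                        clone,
                        "uninduced" if L == 0 else "induced",
                        float(L),
                        config.od600,
                        float(y * config.od600),
                    )
                )
    return pd.DataFrame(
        rows, columns=["clone_id", "condition", "ligand_conc", "od600", "gfp_raw"]
    )


# ---------------------------------------------------------------------------
# labeled operator sets (inducible vs uninducible)

#: Within-class fold-induction modifier keyed by the base at the tuning
#: position; gives the regression a graded, sequence-determined target.
_TUNER_EFFECT = {"A": 1.5, "C": 1.2, "G": 0.8, "T": 0.5}


def generate_labeled_operator_sets(
    n_per_class: int = 100,
    core: str = "TACA",
    inducible_window: tuple[int, int] = (0, 4),
    uninducible_window: tuple[int, int] = (2, 6),
    flank_rules: dict | None = None,
    length: int = 16,
    tuner_position: int = 8,
    fi_mean_inducible: float = 20.0,
    fi_mean_uninducible: float = 1.05,
    fi_cv: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Gap-free operator sequences with planted positional/flank signal.

    Inducible operators carry ``core`` at ``inducible_window`` with the
    inducible flank rule applied and a high fold induction modulated by the
    base at ``tuner_position``; uninducible operators carry the core shifted
    to ``uninducible_window`` with the contrasting flanks and fold induction
    about 1.  Returns columns id, sequence, label, fold_induction.
    """
    if flank_rules is None:
        flank_rules = {
            "inducible": {6: "G", 12: "C"},
            "uninducible": {6: "T", 12: "A"},
        }
    for cls, rules in flank_rules.items():
        win = inducible_window if cls == "inducible" else uninducible_window
        for pos, base in rules.items():
            if win[0] <= pos < win[1]:
                raise ValueError(
                    f"flank rule at {pos} contradicts the {cls} core window"
                )
    for win in (inducible_window, uninducible_window):
        if win[1] - win[0] != len(core) or win[1] > length:
            raise ValueError("core window must fit the sequence length")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(fi_cv**2)))
    rows = []
    for cls, win, fi_mean in (
        ("inducible", inducible_window, fi_mean_inducible),
        ("uninducible", uninducible_window, fi_mean_uninducible),
    ):
        for i in range(n_per_class):
            seq = list(rng.choice(list(BASES), size=length))
            seq[win[0] : win[1]] = list(core)
            for pos, base in flank_rules[cls].items():
                seq[pos] = base
            s = "".join(seq)
            fi = fi_mean
            if cls == "inducible":
                fi *= _TUNER_EFFECT[s[tuner_position]]
            fi *= float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
            rows.append((f"{cls[:3]}_{i:03d}", s, cls, fi))
    return pd.DataFrame(rows, columns=["id", "sequence", "label", "fold_induction"])


__all__ = [
    "DEFAULT_BASE_FREQS",
    "DEFAULT_LIBRARY_LENGTHS",
    "ExpressionSimConfig",
    "PlantedMotif",
    "SelectionSimConfig",
    "biased_background",
    "default_planted_motif",
    "expected_expression",
    "generate_background_library",
    "generate_labeled_operator_sets",
    "occupancy",
    "sample_reads",
    "selection_weights",
    "simulate_expression",
    "simulate_selection",
    "uniform_background",
]
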