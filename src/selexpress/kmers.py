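"""Gapped k-mer counting and Markov-background enrichment.

The central statistic of the selection analysis: patterns of the form
``l-mer  m-spacer  n-mer`` (``l, n`` in {4, 5}, spacer of ``m`` wildcard
positions, written with ``x``, e.g. ``ACTACxxxACGC``) are counted once per
read in the selected sample, and their counts are divided by the number of
occurrences expected under a fifth-order Markov model trained on the
unselected starting library.  Enrichment > 1 indicates affinity selection.
"""

from __future__ import annotations

import itertools
from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_CODE_ARR = np.full(256, -1, dtype=np.int64)
for _b, _i in _CODE.items():
    _CODE_ARR[ord(_b)] = _i

DEFAULT_L_VALUES = (4, 5)
DEFAULT_N_VALUES = (4, 5)
DEFAULT_COUNT_THRESHOLD = 50


class UnsupportedPatternError(ValueError):
    """Pattern too short for the Markov factorization."""


@dataclass(frozen=True)
class GappedKmer:
    """An l-mer / m-spacer / n-mer pattern; wildcards written as ``x``."""

    left: str
    gap: int
    right: str

    def __post_init__(self):
        if self.gap < 0:
            raise ValueError("spacer length must be >= 0")
        for part in (self.left, self.right):
            if any(c not in _CODE for c in part):
                raise ValueError(f"non-ACGT character in pattern part {part!r}")

    @property
    def text(self) -> str:
        return self.left + "x" * self.gap + self.right

    @property
    def span(self) -> int:
        return len(self.left) + self.gap + len(self.right)

    @property
    def k(self) -> int:
        return self.span

    @classmethod
    def from_text(cls, text: str) -> "GappedKmer":
        """Parse canonical text form; wildcards may be written x or X.

        An ungapped text is split so that the left part takes at most 5
        characters (the l in {4,5}, n in {4,5} grammar).
        """
        norm = text.strip().upper().replace("X", "x")
        if "x" not in norm:
            l = min(5, len(norm) - 4)
            if l < 4:
                raise ValueError(f"pattern {text!r} too short for l,n >= 4")
            return cls(norm[:l], 0, norm[l:])
        i = norm.index("x")
        j = len(norm) - norm[::-1].index("x")
        if set(norm[i:j]) != {"x"}:
            raise ValueError(f"wildcards must be contiguous in {text!r}")
        return cls(norm[:i], j - i, norm[j:])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.text


def _encode(seq: str) -> np.ndarray:
    arr = _CODE_ARR[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError(f"non-ACGT character in read {seq!r}")
    return arr


def enumerate_gapped_kmers(
    read: str,
    l_values: Iterable[int] = DEFAULT_L_VALUES,
    n_values: Iterable[int] = DEFAULT_N_VALUES,
) -> set[str]:
    """All distinct gapped k-mer pattern texts instantiated by one read.

    Every (l, n) pair, every spacer m in 0..N-l-n and every in-read offset is
    emitted; duplicates within the read collapse (first-occurrence counting).
    """
    read = read.upper()
    if any(c not in _CODE for c in read):
        raise ValueError(f"non-ACGT character in read {read!r}")
    N = len(read)
    out: set[str] = set()
    for l in l_values:
        for n in n_values:
            for m in range(0, N - l - n + 1):
                span = l + m + n
                gap = "x" * m
                for o in range(N - span + 1):
                    out.add(read[o : o + l] + gap + read[o + l + m : o + span])
    return out


def _read_groups(reads) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Group reads by length -> (length, codes matrix, multiplicities)."""
    if isinstance(reads, Mapping):
        uniq = reads
    else:
        uniq = Counter(reads)
    by_len: dict[int, tuple[list[str], list[int]]] = {}
    for seq, cnt in uniq.items():
        s = seq.upper()
        by_len.setdefault(len(s), ([], []))[0].append(s)
        by_len[len(s)][1].append(cnt)
    groups = []
    for L, (seqs, cnts) in sorted(by_len.items()):
        mat = _CODE_ARR[
            np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
        ].reshape(len(seqs), L)
        if (mat < 0).any():
            bad = np.argwhere(mat < 0)[0]
            raise ValueError(f"non-ACGT character in read {seqs[bad[0]]!r}")
        groups.append((L, mat, np.asarray(cnts, dtype=np.float64)))
    return groups


def _window_codes(mat: np.ndarray, width: int) -> np.ndarray:
    """Base-4 integer code of every sliding window of the given width."""
    n, L = mat.shape
    if L < width:
        return np.empty((n, 0), dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(mat, width, axis=1)
    weights = 4 ** np.arange(width - 1, -1, -1, dtype=np.int64)
    return win @ weights


def _decode(code: int, width: int) -> str:
    out = []
    for _ in range(width):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def count_patterns(
    reads,
    l_values: Iterable[int] = DEFAULT_L_VALUES,
    n_values: Iterable[int] = DEFAULT_N_VALUES,
    count_threshold: int = DEFAULT_COUNT_THRESHOLD,
) -> dict[str, int]:
    """Per-pattern read counts (first occurrence per read), filtered.

    ``reads`` may be an iterable of sequences or a mapping sequence -> count.
    Patterns observed in fewer than ``count_threshold`` reads are dropped.
    Counts pool across read lengths (the equimolar 16-19 bp libraries are
    analysed jointly).
    """
    groups = _read_groups(reads)
    if not groups:
        return {}
    max_len = max(L for L, _, _ in groups)
    # cache sliding-window codes per (length, width)
    wincache: dict[tuple[int, int], np.ndarray] = {}
    for (L, mat, _), w in itertools.product(groups, set(l_values) | set(n_values)):
        wincache[(L, w)] = _window_codes(mat, w)

    counts: dict[str, int] = {}
    for l in sorted(set(l_values)):
        for n in sorted(set(n_values)):
            for m in range(0, max_len - l - n + 1):
                span = l + m + n
                acc: np.ndarray | None = None
                for L, mat, mult in groups:
                    noff = L - span + 1
                    if noff <= 0:
                        continue
                    lv = wincache[(L, l)][:, :noff]
                    rv = wincache[(L, n)][:, l + m : l + m + noff]
                    V = lv * (4**n) + rv
                    V = np.sort(V, axis=1)
                    keep = np.ones(V.shape, dtype=bool)
                    keep[:, 1:] = V[:, 1:] != V[:, :-1]
                    vals = V[keep]
                    wts = np.repeat(mult, keep.sum(axis=1))
                    binned = np.bincount(vals, weights=wts, minlength=4 ** (l + n))
                    acc = binned if acc is None else acc + binned
                if acc is None:
                    continue
                hits = np.nonzero(acc >= max(count_threshold, 1))[0]
                gap = "x" * m
                for code in hits:
                    pat = _decode(int(code // 4**n), l) + gap + _decode(
                        int(code % 4**n), n
                    )
                    counts[pat] = int(round(acc[code]))
    return counts


class MarkovBackground:
    """Order-``order`` Markov model of the unselected library.

    ``conditional[s, b]`` is P(next base = b | previous ``order`` bases encode
    to state s); ``initial[s]`` is the stationary probability of the state as
    estimated from every window of the background reads, so that patterns
    occurring at arbitrary offsets can be scored.
    """

    def __init__(self, conditional: np.ndarray, initial: np.ndarray, order: int = 5):
        conditional = np.asarray(conditional, dtype=np.float64)
        initial = np.asarray(initial, dtype=np.float64)
        S = 4**order
        if conditional.shape != (S, 4) or initial.shape != (S,):
            raise ValueError("model arrays inconsistent with order")
        if not np.allclose(conditional.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("conditional rows must each sum to 1")
        if not np.isclose(initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial state probabilities must sum to 1")
        self.order = order
        self.conditional = conditional
        self.initial = initial

    @classmethod
    def train(
        cls, reads, order: int = 5, pseudocount: float = 1.0
    ) -> "MarkovBackground":
        """Smoothed maximum-likelihood fit from background reads.

        Every (context, next base) window contributes; the default
        pseudocount of 1 per cell keeps all pattern expectations positive.
        """
        S = 4**order
        trans = np.zeros(S * 4, dtype=np.float64)
        init = np.zeros(S, dtype=np.float64)
        n_windows = 0
        for L, mat, mult in _read_groups(reads):
            if L < order:
                continue
            ctx = _window_codes(mat, order)
            init += np.bincount(
                ctx.ravel(),
                weights=np.repeat(mult, ctx.shape[1]),
                minlength=S,
            )
            if L < order + 1:
                continue
            pair = ctx[:, :-1] * 4 + mat[:, order:]
            trans += np.bincount(
                pair.ravel(),
                weights=np.repeat(mult, pair.shape[1]),
                minlength=S * 4,
            )
            n_windows += pair.size
        if init.sum() == 0:
            raise ValueError("no background reads of at least the model order")
        trans = trans.reshape(S, 4) + pseudocount
        row_tot = trans.sum(axis=1, keepdims=True)
        # contexts never observed (possible only at pseudocount 0) carry no
        # information; give them a uniform conditional
        empty = row_tot[:, 0] == 0
        trans[empty] = 0.25
        row_tot[empty] = 1.0
        conditional = trans / row_tot
        init = init + pseudocount / 4.0
        initial = init / init.sum()
        return cls(conditional, initial, order=order)

    # -- pattern scoring ---------------------------------------------------

    def _pattern_codes(self, pattern) -> list[int | None]:
        text = pattern.text if isinstance(pattern, GappedKmer) else str(pattern)
        codes: list[int | None] = []
        for c in text.upper().replace("X", "x"):
            if c == "x":
                codes.append(None)
            elif c in _CODE:
                codes.append(_CODE[c])
            else:
                raise ValueError(f"illegal pattern character {c!r}")
        return codes

    def pattern_probability(self, pattern) -> float:
        """Chain-factorized probability of a (gapped) pattern.

        Follows the factor decomposition of the enrichment method: the
        initial ``order``-mer probability times one conditional per later
        position, with every wildcard factor equal to 1.  Wildcards inside
        later contexts are marginalized over the chain (the sum of the four
        conditional probabilities at a wildcard step is exactly 1, so the
        wildcard still contributes a unit factor overall).
        """
        codes = self._pattern_codes(pattern)
        if len(codes) < self.order + 1:
            raise UnsupportedPatternError(
                f"pattern span {len(codes)} < order+1 = {self.order + 1}"
            )
        S = 4**self.order
        fwd = self.initial.copy()
        states = np.arange(S)
        for t in range(self.order):
            b = codes[t]
            if b is not None:
                sel = (states >> (2 * (self.order - 1 - t))) & 3
                fwd = np.where(sel == b, fwd, 0.0)
        suffix = states % (S // 4)
        for t in range(self.order, len(codes)):
            b = codes[t]
            new = np.zeros(S)
            targets = suffix * 4
            if b is None:
                for bb in range(4):
                    np.add.at(new, targets + bb, fwd * self.conditional[:, bb])
            else:
                np.add.at(new, targets + b, fwd * self.conditional[:, b])
            fwd = new
        return float(fwd.sum())


def expected_count(
    model: MarkovBackground,
    pattern,
    length_counts: Mapping[int, float] | int,
    convention: str = "single-position",
) -> float:
    """Expected number of reads counted for a pattern.

    ``single-position`` multiplies the pattern probability by the total read
    count (the method's literal description).  ``per-read-any-offset``
    accounts for every offset the pattern can occupy in each read length:
    ``sum_L n_L * (1 - (1 - p)^offsets(L))`` with the stationary initial
    distribution at every offset.
    """
    p = model.pattern_probability(pattern)
    span = (
        pattern.span if isinstance(pattern, GappedKmer) else len(str(pattern))
    )
    if isinstance(length_counts, (int, np.integer)):
        length_counts = {span: float(length_counts)} if convention == "single-position" else None
        if length_counts is None:
            raise ValueError("per-read-any-offset needs per-length read counts")
    total = float(sum(length_counts.values()))
    if total < 1:
        raise ValueError("need at least one read")
    if convention == "single-position":
        return p * total
    if convention == "per-read-any-offset":
        exp = 0.0
        for L, nL in length_counts.items():
            noff = L - span + 1
            if noff > 0:
                exp += nL * (1.0 - (1.0 - p) ** noff)
        return exp
    raise ValueError(f"unknown convention {convention!r}")


def enrichment_table(
    sample_counts: Mapping[str, int],
    model: MarkovBackground,
    length_counts: Mapping[int, float],
    convention: str = "single-position",
) -> pd.DataFrame:
    """Observed/expected/enrichment per retained pattern, sorted descending.

    Patterns whose expected count is zero (impossible after smoothing, but
    guarded) are excluded with a warning column rather than dividing by zero.
    """
    import warnings

    rows = []
    for pat, obs in sample_counts.items():
        gk = GappedKmer.from_text(pat)
        exp = expected_count(model, gk, length_counts, convention=convention)
        if exp <= 0.0:
            warnings.warn(f"pattern {pat} has zero expected count; excluded")
            continue
        rows.append(
            (
                gk.text,
                len(gk.left),
                gk.gap,
                len(gk.right),
                int(obs),
                exp,
                obs / exp,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["pattern", "l", "m", "n", "observed", "expected", "enrichment"],
    )
    df = df.sort_values(
        ["enrichment", "observed", "pattern"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return df
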