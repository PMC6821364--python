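"""End-to-end motif enrichment model: reads in, seed + PWM out.

``MotifEnrichmentModel`` bundles the full analysis of one selected sample:
train the order-5 Markov background on the starting library, count gapped
k-mers in the selected reads, filter at the count threshold, compute
observed/expected enrichment, pick the top-enriched seed and weight a PWM
from its 1-mismatch variants.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping

import pandas as pd

from . import kmers
from .kmers import GappedKmer, MarkovBackground, count_patterns, enrichment_table
from .pwm import PositionWeightMatrix, build_pwm, mismatch_enrichments, select_seed


def _length_counts(reads) -> dict[int, float]:
    lc: Counter = Counter()
    if isinstance(reads, Mapping):
        for s, c in reads.items():
            lc[len(s)] += c
    else:
        for s in reads:
            lc[len(s)] += 1
    return dict(lc)


class MotifEnrichmentModel:
    """Gapped k-mer enrichment analysis of one selected sample.

    Parameters
    ----------
    sample_reads : iterable of str or mapping str -> count
        Randomized-region reads of the selected round.
    background_reads : iterable of str or mapping, optional
        Starting-library reads used to train the Markov background.  Either
        this or a pre-trained ``background`` model must be given.
    count_threshold : int
        Patterns seen in fewer reads are dropped (default 50).
    convention : str
        Expected-count convention, ``single-position`` (literal) or
        ``per-read-any-offset``.
    """

    def __init__(
        self,
        sample_reads,
        background_reads=None,
        background: MarkovBackground | None = None,
        l_values=kmers.DEFAULT_L_VALUES,
        n_values=kmers.DEFAULT_N_VALUES,
        count_threshold: int = kmers.DEFAULT_COUNT_THRESHOLD,
        convention: str = "single-position",
        order: int = 5,
        pseudocount: float = 1.0,
    ):
        if background is None and background_reads is None:
            raise ValueError("need background_reads or a trained background model")
        self.sample_reads = (
            sample_reads if isinstance(sample_reads, Mapping) else Counter(sample_reads)
        )
        self.background_reads = background_reads
        self.background = background
        self.l_values = tuple(l_values)
        self.n_values = tuple(n_values)
        self.count_threshold = count_threshold
        self.convention = convention
        self.order = order
        self.pseudocount = pseudocount

    def fit(self, build_motif: bool = True) -> "MotifEnrichmentResults":
        model = self.background
        if model is None:
            model = MarkovBackground.train(
                self.background_reads, order=self.order, pseudocount=self.pseudocount
            )
        counts = count_patterns(
            self.sample_reads,
            l_values=self.l_values,
            n_values=self.n_values,
            count_threshold=self.count_threshold,
        )
        length_counts = _length_counts(self.sample_reads)
        table = enrichment_table(
            counts, model, length_counts, convention=self.convention
        )
        seed = pwm_ = None
        if build_motif and len(table):
            seed = select_seed(table)
            mm = mismatch_enrichments(
                seed,
                counts,
                model,
                length_counts,
                count_threshold=self.count_threshold,
                convention=self.convention,
            )
            pwm_ = build_pwm(mm, seed=seed)
        return MotifEnrichmentResults(
            model=self,
            background_model=model,
            pattern_counts=counts,
            length_counts=length_counts,
            table=table,
            seed=seed,
            pwm=pwm_,
        )


class MotifEnrichmentResults:
    """Fitted enrichment analysis: table, seed pattern and PWM."""

    def __init__(
        self,
        model: MotifEnrichmentModel,
        background_model: MarkovBackground,
        pattern_counts: dict[str, int],
        length_counts: dict[int, float],
        table: pd.DataFrame,
        seed: GappedKmer | None,
        pwm: PositionWeightMatrix | None,
    ):
        self.model = model
        self.background_model = background_model
        self.pattern_counts = pattern_counts
        self.length_counts = length_counts
        self.table = table
        self.seed = seed
        self.pwm = pwm

    @property
    def n_retained(self) -> int:
        return len(self.table)

    def summary(self) -> str:
        total = sum(self.length_counts.values())
        lines = [
            "Gapped k-mer enrichment analysis",
            "=" * 40,
            f"sample reads:        {int(total)}",
            f"count threshold:     {self.model.count_threshold}",
            f"expected convention: {self.model.convention}",
            f"patterns retained:   {self.n_retained}",
        ]
        if self.seed is not None:
            lines += [
                f"seed pattern:        {self.seed.text}",
                f"seed enrichment:     {self.table.iloc[0]['enrichment']:.2f}",
                f"PWM consensus:       {self.pwm.consensus}",
            ]
        if len(self.table):
            lines += ["", "top patterns:", self.table.head(10).to_string(index=False)]
        return "\n".join(lines)


__all__ = ["MotifEnrichmentModel", "MotifEnrichmentResults"]
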