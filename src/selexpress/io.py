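"""File formats and demultiplexing.

FASTQ/FASTA reading and writing goes through Biopython; this module adds
the experiment-specific pieces: barcode demultiplexing of selection reads
into per-sample randomized regions, aligned-FASTA ingestion for the
regression, MEME-minimal / tab motif serialization, and the
ExpressionRecord CSV table.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pwm import PositionWeightMatrix

_DNA = set("ACGT")


@dataclass(frozen=True)
class SampleRead:
    """A demultiplexed read: barcode, randomized region, owning sample."""

    barcode: str
    random_region: str
    sample_id: str

    def __post_init__(self):
        if len(self.barcode) != 8:
            raise ValueError("barcode must be exactly 8 bases")
        if not set(self.random_region) <= _DNA:
            raise ValueError("random region may contain only A/C/G/T")


@dataclass
class DemuxResult:
    """Per-sample reads plus discard bookkeeping."""

    per_sample: dict = field(default_factory=dict)
    n_unmatched: int = 0
    n_ambiguous_region: int = 0
    n_total: int = 0

    @property
    def n_discarded(self) -> int:
        return self.n_unmatched + self.n_ambiguous_region

    def sample_counts(self) -> dict:
        return {k: len(v) for k, v in self.per_sample.items()}


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads,
    barcode_map,
    region: tuple[int, int | None] = (8, None),
    barcode_span: tuple[int, int] = (0, 8),
    max_mismatch: int = 0,
) -> DemuxResult:
    """Assign reads to samples by barcode; extract the randomized region.

    ``reads`` is a FASTQ/FASTA path, handle, or iterable of sequence
    strings.  ``barcode_map`` maps 8 bp barcode -> sample id (an iterable
    of pairs is accepted; duplicate barcodes are a configuration error).
    ``region`` is the 0-based half-open randomized-region slice (end None
    = to the read end).  Reads with an unmatched/ambiguous barcode or any
    non-ACGT character in the region go to the discard tallies.  Barcode
    matching is exact unless ``max_mismatch`` > 0, in which case a read is
    assigned only when exactly one barcode is within the tolerance.
    """
    if not isinstance(barcode_map, dict):
        pairs = list(barcode_map)
        barcode_map = {}
        for bc, sample in pairs:
            if bc in barcode_map:
                raise ValueError(f"duplicate barcode {bc!r} in barcode map")
            barcode_map[bc] = sample
    if len(set(barcode_map)) != len(barcode_map):  # dict: vacuously true
        raise ValueError("barcodes must be mutually distinct")
    for bc in barcode_map:
        if len(bc) != len(range(*barcode_span)):
            raise ValueError(f"barcode {bc!r} does not fit barcode span {barcode_span}")

    if isinstance(reads, (str, Path)):
        fmt = "fasta" if str(reads).endswith((".fa", ".fasta", ".afa")) else "fastq"
        seqs = (str(rec.seq) for rec in SeqIO.parse(str(reads), fmt))
    elif hasattr(reads, "read"):
        seqs = (str(rec.seq) for rec in SeqIO.parse(reads, "fastq"))
    else:
        seqs = iter(reads)

    res = DemuxResult(per_sample={sid: [] for sid in barcode_map.values()})
    b0, b1 = barcode_span
    r0, r1 = region
    for seq in seqs:
        seq = str(seq).upper()
        res.n_total += 1
        bc = seq[b0:b1]
        sample = barcode_map.get(bc)
        if sample is None and max_mismatch > 0:
            hits = [
                sid
                for known, sid in barcode_map.items()
                if _hamming(bc, known) <= max_mismatch
            ]
            sample = hits[0] if len(hits) == 1 else None
        if sample is None:
            res.n_unmatched += 1
            continue
        regionseq = seq[r0:] if r1 is None else seq[r0:r1]
        if not set(regionseq) <= _DNA or not regionseq:
            res.n_ambiguous_region += 1
            continue
        res.per_sample[sample].append(SampleRead(bc, regionseq, sample))
    return res


# ---------------------------------------------------------------------------
# FASTA / aligned FASTA


def read_aligned_fasta(path) -> tuple[list[tuple[str, str]], int | None]:
    """Gap-filled alignment records as (id, sequence); validates ragged input.

    Returns the records and the aligned length (None for an empty file).
    """
    records = []
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError(
                f"record {rec.id!r} has length {len(seq)}, expected {length}"
            )
        records.append((rec.id, seq))
    return records, length


def write_fasta(records, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=str(rid), description="") for rid, seq in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(seqs, path, prefix: str = "read", quality: int = 40) -> None:
    """Plain FASTQ with constant quality (qualities are ignored downstream)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(seqs):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{chr(33 + quality) * len(seq)}\n")


# ---------------------------------------------------------------------------
# motif serialization


def write_motif(pwm: PositionWeightMatrix, path, dialect: str = "meme") -> None:
    """Serialize a PWM (>= 6 significant digits) as MEME-minimal or tab matrix."""
    probs = np.asarray(pwm.probs, dtype=float)
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("PWM columns must be normalized before writing")
    if dialect == "meme":
        lines = [
            "MEME version 4",
            "",
            f"ALPHABET= {pwm.alphabet}",
            "",
            "MOTIF motif_1",
            f"letter-probability matrix: alength= {probs.shape[1]} w= {len(probs)}",
        ]
        for row in probs:
            lines.append(" ".join(f"{p:.6f}" for p in row))
    elif dialect == "tab":
        lines = ["\t".join(["pos"] + list(pwm.alphabet))]
        for i, row in enumerate(probs):
            lines.append("\t".join([str(i)] + [f"{p:.6g}" for p in row]))
    else:
        raise ValueError(f"unknown motif dialect {dialect!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_motif(path, dialect: str = "meme") -> PositionWeightMatrix:
    text = Path(path).read_text().splitlines()
    if dialect == "meme":
        alphabet = "ACGT"
        rows = []
        in_matrix = False
        for line in text:
            if line.startswith("ALPHABET="):
                alphabet = line.split("=", 1)[1].strip()
            elif line.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix:
                parts = line.split()
                if not parts:
                    break
                rows.append([float(x) for x in parts])
        probs = np.asarray(rows)
    elif dialect == "tab":
        header = text[0].split("\t")
        alphabet = "".join(header[1:])
        probs = np.asarray(
            [[float(x) for x in line.split("\t")[1:]] for line in text[1:] if line]
        )
    else:
        raise ValueError(f"unknown motif dialect {dialect!r}")
    return PositionWeightMatrix(probs, alphabet=alphabet)


# ---------------------------------------------------------------------------
# expression tables

EXPRESSION_COLUMNS = ["clone_id", "condition", "ligand_conc", "od600", "gfp_raw"]


def read_expression_table(path) -> pd.DataFrame:
    """ExpressionRecord CSV with validation of the documented invariants."""
    df = pd.read_csv(path)
    missing = set(EXPRESSION_COLUMNS) - {"ligand_conc"} - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    bad = ~df["condition"].isin(["uninduced", "induced"])
    if bad.any():
        raise ValueError(
            f"illegal condition values: {df.loc[bad, 'condition'].unique().tolist()}"
        )
    if (df["od600"] <= 0).any():
        raise ValueError("od600 must be > 0")
    if (df["gfp_raw"] < 0).any():
        raise ValueError("gfp_raw must be >= 0")
    if "ligand_conc" in df.columns and (df["ligand_conc"].dropna() < 0).any():
        raise ValueError("ligand_conc must be >= 0")
    return df


def write_expression_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in EXPRESSION_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


__all__ = [
    "DemuxResult",
    "EXPRESSION_COLUMNS",
    "SampleRead",
    "demultiplex",
    "read_aligned_fasta",
    "read_expression_table",
    "read_motif",
    "write_expression_table",
    "write_fasta",
    "write_fastq",
    "write_motif",
]
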