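"""Read preprocessing: quality filtering, trimming, subsampling, species tagging.

Raw Illumina reads are quality filtered (discard a read if any base has
Phred quality <= ``min_phred`` or it contains more than ``max_n`` ambiguous
bases), trimmed to a uniform length (91 bp by default, keeping the 5' end),
subsampled to a fixed genome proportion so that read counts are comparable
across genomes of different sizes, and prefixed with a five-letter species
code so that per-species counts can be recovered after pooled clustering.

Deliberately light-touch: higher-stringency quality filtering biases repeat
abundance estimates because satellite and AT/GC-rich repeats tend to have
lower base qualities.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

SPECIES_CODE_RE = re.compile(r"^[A-Za-z]{5}$")

DEFAULT_MIN_PHRED = 10
DEFAULT_MAX_N = 3
DEFAULT_TARGET_LENGTH = 91
DEFAULT_PROPORTION = 0.02


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


@dataclass
class Read:
    """A single read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )


@dataclass
class ReadSet:
    """An ordered collection of reads from one species.

    ``provenance`` maps read_id to the true source repeat family (or None for
    single-copy background) when the reads were simulated; it is carried
    through preprocessing so that cluster-recovery tests can score against
    ground truth.
    """

    reads: list[Read] = field(default_factory=list)
    species_code: str | None = None
    read_length: int | None = None
    provenance: dict[str, str | None] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def uniform_length(self) -> int:
        lengths = {len(r.sequence) for r in self.reads}
        if len(lengths) > 1:
            raise ValueError(f"non-uniform read lengths: {sorted(lengths)}")
        return lengths.pop() if lengths else 0


def _open_maybe_gz(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path, species_code: str | None = None) -> ReadSet:
    """Load a FASTQ file (gz-transparent) into a ReadSet."""
    reads = []
    with _open_maybe_gz(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            reads.append(
                Read(
                    read_id=rec.id,
                    sequence=str(rec.seq),
                    qualities=tuple(rec.letter_annotations["phred_quality"]),
                )
            )
    rs = ReadSet(reads=reads, species_code=species_code)
    if reads:
        lengths = {len(r.sequence) for r in reads}
        if len(lengths) == 1:
            rs.read_length = lengths.pop()
    return rs


def write_fastq(rs: ReadSet, path) -> None:
    """Write a ReadSet as Sanger (Phred+33) FASTQ, gz-transparent."""
    records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.read_id,
            description="",
            letter_annotations={"phred_quality": list(r.qualities)},
        )
        for r in rs.reads
    ]
    with _open_maybe_gz(path, "wt") as fh:
        SeqIO.write(records, fh, "fastq")


def preprocess_reads(
    raw: ReadSet,
    min_phred: int = DEFAULT_MIN_PHRED,
    max_n: int = DEFAULT_MAX_N,
    target_length: int = DEFAULT_TARGET_LENGTH,
    per_read_mean: bool = False,
) -> ReadSet:
    """Quality-filter and trim reads to a uniform length.

    A read is discarded if its minimum per-base Phred score is <= ``min_phred``
    (i.e. only reads with every base strictly above the threshold survive), or
    if it contains more than ``max_n`` N bases, or if it is shorter than
    ``target_length``. Survivors are truncated to their first
    ``target_length`` bases. Input order is preserved.

    ``per_read_mean=True`` applies the Phred threshold to the read-mean
    quality instead of the per-base minimum.
    """
    kept: list[Read] = []
    for r in raw.reads:
        if per_read_mean:
            q_ok = float(np.mean(r.qualities)) > min_phred
        else:
            q_ok = min(r.qualities) > min_phred
        if not q_ok:
            continue
        if r.sequence.upper().count("N") > max_n:
            continue
        if len(r.sequence) < target_length:
            continue
        kept.append(
            Read(
                read_id=r.read_id,
                sequence=r.sequence[:target_length],
                qualities=r.qualities[:target_length],
            )
        )
    if not kept:
        logger.warning("preprocess_reads: no reads passed filtering")
    out = ReadSet(
        reads=kept,
        species_code=raw.species_code,
        read_length=target_length,
        provenance={r.read_id: raw.provenance[r.read_id] for r in kept}
        if raw.provenance
        else {},
    )
    return out


def subsample_reads(
    rs: ReadSet,
    c_value_bp: int,
    seed: int,
    proportion: float = DEFAULT_PROPORTION,
) -> ReadSet:
    """Subsample to a fixed genome proportion.

    The target read number is ``round(proportion * c_value_bp / read_length)``
    (halves away from zero), drawn uniformly without replacement. Sampling a
    fixed genome proportion — rather than a fixed read number — makes cluster
    read counts comparable across genomes of different 1C sizes.
    """
    read_length = rs.uniform_length()
    if read_length == 0:
        logger.warning("subsample_reads: empty input ReadSet")
        return replace(rs, reads=[], provenance={})
    n = round_half_away(proportion * c_value_bp / read_length)
    if n == 0:
        logger.warning("subsample_reads: target subsample size is 0")
        return replace(rs, reads=[], provenance={})
    if n > len(rs.reads):
        raise ValueError(
            f"subsample needs {n} reads but only {len(rs.reads)} available "
            f"(shortfall {n - len(rs.reads)}): insufficient sequencing depth"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(rs.reads), size=n, replace=False))
    reads = [rs.reads[i] for i in idx]
    return ReadSet(
        reads=reads,
        species_code=rs.species_code,
        read_length=read_length,
        provenance={r.read_id: rs.provenance[r.read_id] for r in reads}
        if rs.provenance
        else {},
    )


def tag_species(rs: ReadSet, code: str) -> ReadSet:
    """Prefix every read_id with a five-letter species code."""
    if not SPECIES_CODE_RE.match(code):
        raise ValueError(f"species code must be exactly 5 letters, got {code!r}")
    reads = [
        Read(read_id=f"{code}_{r.read_id}", sequence=r.sequence, qualities=r.qualities)
        for r in rs.reads
    ]
    provenance = (
        {f"{code}_{rid}": fam for rid, fam in rs.provenance.items()}
        if rs.provenance
        else {}
    )
    return ReadSet(
        reads=reads,
        species_code=code,
        read_length=rs.read_length,
        provenance=provenance,
    )
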