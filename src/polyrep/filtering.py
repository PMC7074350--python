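"""Cluster filtering: contaminants, low-abundance and species-specific clusters.

Comparative repeat clusters are only informative when they represent nuclear
repeats observed in more than one species of the cross. This module flags
contaminant clusters (organellar DNA, sequence artefacts) by shared k-mer
content with user-supplied reference sequences, then applies the abundance
and presence filters: a species "has" a cluster only when it contributes at
least ``min_reads`` reads; clusters present in fewer than two species
(species-specific clusters) and clusters absent from the tetraploid are
removed from the regression set. Clusters present in both parents but lost
from the tetraploid are kept aside for the deviation curves — complete loss
of a parental repeat is a genuine downsizing signal, not a missing value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq

from .cluster import Cluster, ClusterTable
from .prep import ReadSet

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 10
DEFAULT_CONTAM_K = 17
DEFAULT_CONTAM_MIN_FRACTION = 0.5

REASON_CONTAMINANT = "contaminant"
REASON_SPECIES_SPECIFIC = "species_specific"
REASON_ABSENT_TETRAPLOID = "absent_in_tetraploid"
REASON_NOT_ALL_SPECIES = "not_in_all_species"


@dataclass
class CrossDesign:
    """Which species code plays which role in the allopolyploid cross."""

    maternal_code: str
    paternal_code: str
    tetraploid_code: str

    def __post_init__(self) -> None:
        codes = (self.maternal_code, self.paternal_code, self.tetraploid_code)
        if len(set(codes)) != 3:
            raise ValueError(f"cross design codes must be distinct, got {codes}")

    @property
    def codes(self) -> tuple[str, str, str]:
        return (self.maternal_code, self.paternal_code, self.tetraploid_code)

    def validate_against(self, table: ClusterTable) -> None:
        missing = set(self.codes) - set(table.species_codes)
        if missing:
            raise ValueError(
                f"design codes {sorted(missing)} absent from cluster table "
                f"species {table.species_codes}"
            )


@dataclass
class FilterResult:
    """Outcome of filtering: the regression set, the curve set, and a log.

    ``retained`` feeds the parental-bias regressions. ``curve`` additionally
    includes clusters present in both parents but absent from the tetraploid
    (counted with t = 0 in deviation curves). ``removed`` records every
    removal exactly once with one reason.
    """

    retained: ClusterTable
    curve: ClusterTable
    removed: list[tuple[str, str]] = field(default_factory=list)


def canonical_kmers(sequence: str, k: int) -> set[str]:
    """Strand-canonical k-mer set (lexicographic min of k-mer and revcomp)."""
    seq = sequence.upper()
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if set(kmer) - set("ACGT"):
            continue
        rc = str(Seq(kmer).reverse_complement())
        out.add(min(kmer, rc))
    return out


def _load_references(contaminant_refs) -> list[tuple[str, str]]:
    """Accept a FASTA path or an iterable of (name, sequence) pairs."""
    if contaminant_refs is None:
        return []
    if isinstance(contaminant_refs, (str,)) or hasattr(contaminant_refs, "__fspath__"):
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(contaminant_refs), "fasta")]
    return [(name, seq) for name, seq in contaminant_refs]


def flag_contaminants(
    table: ClusterTable,
    reads: ReadSet,
    contaminant_refs=None,
    k: int = DEFAULT_CONTAM_K,
    min_fraction: float = DEFAULT_CONTAM_MIN_FRACTION,
) -> ClusterTable:
    """Flag clusters whose reads match contaminant references.

    A read "matches" if it shares at least one canonical k-mer with any
    reference; a cluster is flagged when the matching fraction of its
    members is >= ``min_fraction``. Nothing is deleted here — flags are
    recorded for :func:`apply_filters`.
    """
    refs = _load_references(contaminant_refs)
    ref_kmers: set[str] = set()
    for _, seq in refs:
        ref_kmers |= canonical_kmers(seq, k)
    if not ref_kmers:
        return ClusterTable(
            clusters=[replace(c, contaminant_flag=False) for c in table.clusters],
            species_codes=table.species_codes,
        )
    seq_by_id = {r.read_id: r.sequence for r in reads.reads}
    flagged = []
    for c in table.clusters:
        n_match = 0
        for rid in c.member_read_ids:
            if rid not in seq_by_id:
                raise KeyError(f"cluster {c.cluster_id}: read {rid} not in ReadSet")
            if canonical_kmers(seq_by_id[rid], k) & ref_kmers:
                n_match += 1
        frac = n_match / c.total if c.total else 0.0
        flagged.append(replace(c, contaminant_flag=frac >= min_fraction))
    return ClusterTable(clusters=flagged, species_codes=table.species_codes)


def apply_filters(
    table: ClusterTable,
    design: CrossDesign,
    min_reads: int = DEFAULT_MIN_READS,
    require_all_species: bool = False,
) -> FilterResult:
    """Apply contaminant, abundance and presence filters.

    A species is "present" in a cluster iff its count >= ``min_reads``.
    Removal order (each cluster removed once, first matching reason):
    contaminant flag; present in fewer than two species (species-specific);
    absent from the tetraploid. With ``require_all_species=True`` the
    stricter reading is used: a cluster must be present in all three
    species. Retained clusters keep their original counts and are annotated
    with the species they are present in.
    """
    design.validate_against(table)
    retained: list[Cluster] = []
    curve_extra: list[Cluster] = []
    removed: list[tuple[str, str]] = []
    for c in table.clusters:
        present = tuple(
            code for code in design.codes if c.count(code) >= min_reads
        )
        annotated = replace(c, present_in=present)
        if c.contaminant_flag:
            removed.append((c.cluster_id, REASON_CONTAMINANT))
            continue
        if require_all_species:
            if len(present) < 3:
                removed.append((c.cluster_id, REASON_NOT_ALL_SPECIES))
                if (
                    design.maternal_code in present
                    and design.paternal_code in present
                ):
                    curve_extra.append(replace(annotated, filter_reason=REASON_NOT_ALL_SPECIES))
                continue
        else:
            if len(present) < 2:
                removed.append((c.cluster_id, REASON_SPECIES_SPECIFIC))
                continue
            if design.tetraploid_code not in present:
                # both parents present, tetraploid lost the repeat: keep for
                # the deviation curve with t counted as observed (possibly 0)
                removed.append((c.cluster_id, REASON_ABSENT_TETRAPLOID))
                curve_extra.append(
                    replace(annotated, filter_reason=REASON_ABSENT_TETRAPLOID)
                )
                continue
        retained.append(annotated)
    for cid, reason in removed:
        logger.info("filtered out %s: %s", cid, reason)
    retained_table = ClusterTable(clusters=retained, species_codes=table.species_codes)
    curve_table = ClusterTable(
        clusters=retained + curve_extra, species_codes=table.species_codes
    )
    return FilterResult(retained=retained_table, curve=curve_table, removed=removed)
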