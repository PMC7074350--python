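"""Shared fixtures and oracle helpers for the polyrep test suite."""

from __future__ import annotations

import numpy as np
import pytest

from polyrep import Cluster, ClusterTable, DeviationRecord

CODES = ("MATER", "PATER", "TETRA")


def table_from_counts(
    counts: list[tuple[int, int, int]],
    codes: tuple[str, str, str] = CODES,
    flags: list[bool] | None = None,
) -> ClusterTable:
    """Build a ClusterTable directly from (maternal, paternal, tetraploid) counts."""
    clusters = []
    for i, (m, p, t) in enumerate(counts, start=1):
        per_species = dict(zip(codes, (m, p, t)))
        members = frozenset(
            f"{code}_c{i}r{j}" for code in codes for j in range(per_species[code])
        )
        clusters.append(
            Cluster(
                cluster_id=f"CL{i}",
                member_read_ids=members,
                counts_by_species=per_species,
                contaminant_flag=bool(flags[i - 1]) if flags else False,
            )
        )
    return ClusterTable(clusters=clusters, species_codes=codes)


def records_from_counts(counts: list[tuple[int, int, int]]) -> list[DeviationRecord]:
    return [
        DeviationRecord(cluster_id=f"CL{i}", m=m, p=p, t=t)
        for i, (m, p, t) in enumerate(counts, start=1)
    ]


def batch_edit_distance(seqs_a: list[str], seqs_b: list[str]) -> np.ndarray:
    """Exact Levenshtein distance for many equal-index pairs at once.

    Full (unbanded) dynamic programme vectorized across pairs; independent
    of the alignment library used by the implementation, so it can serve as
    an all-pairs oracle.
    """
    assert len(seqs_a) == len(seqs_b)
    n_pairs = len(seqs_a)
    la = len(seqs_a[0])
    lb = len(seqs_b[0])
    a = np.frombuffer("".join(seqs_a).encode(), dtype=np.uint8).reshape(n_pairs, la)
    b = np.frombuffer("".join(seqs_b).encode(), dtype=np.uint8).reshape(n_pairs, lb)
    idx = np.arange(lb + 1, dtype=np.int16)
    prev = np.broadcast_to(idx, (n_pairs, lb + 1)).astype(np.int16)
    cand = np.empty_like(prev)
    for i in range(1, la + 1):
        # candidate without the left-neighbour term, then fold the
        # cur[j-1] + 1 dependency in via a running minimum of (cand - j) + j
        cand[:, 0] = i
        np.minimum(
            prev[:, 1:] + 1,
            prev[:, :-1] + (a[:, i - 1 : i] != b),
            out=cand[:, 1:],
        )
        cand -= idx
        prev = np.minimum.accumulate(cand, axis=1)
        prev += idx
    return prev[:, -1].astype(int)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
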