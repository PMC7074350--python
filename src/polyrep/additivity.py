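"""Additivity statistics: expected cluster sizes, deviations, cumulative curves.

Because each species is sampled at the same genome proportion, cluster read
counts are directly comparable across genomes, and the strict-additivity
null for an allotetraploid is that each repeat cluster's size equals the sum
of its sizes in the two parental genomes: E = m + p. The deviation
D = t - E is positive when a repeat amplified after polyploidisation and
negative when it was lost. Summing deviations cumulatively from the
smallest expected cluster upward yields a curve whose shape summarizes the
genome-size trajectory: a flat walk around zero for a faithfully additive
genome, a late rise for upsizing driven by high-copy repeats, a late fall
for downsizing.

The same arithmetic applied to 1C genome sizes gives the genome-size
deviation percentage, e.g. an observed 1C of 5.3 Gbp against an expected
parental sum of 4.1 Gbp is a +29% upsizing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import ClusterTable
from .filtering import CrossDesign


@dataclass
class DeviationRecord:
    """Per-cluster counts with expected size and deviation (exact integers)."""

    cluster_id: str
    m: int
    p: int
    t: int

    def __post_init__(self) -> None:
        if min(self.m, self.p, self.t) < 0:
            raise ValueError(f"{self.cluster_id}: negative counts")

    @property
    def E(self) -> int:
        return self.m + self.p

    @property
    def D(self) -> int:
        return self.t - self.E


@dataclass
class DeviationCurve:
    """Cumulative deviation vs cumulative expected size, smallest cluster first."""

    records: list[DeviationRecord]
    cum_E: np.ndarray
    cum_D: np.ndarray

    @property
    def abs_cum_D(self) -> np.ndarray:
        return np.abs(self.cum_D)

    @property
    def ln_cum_E(self) -> np.ndarray:
        """Natural log of cumulative expected size (the plotting x-axis)."""
        with np.errstate(divide="ignore"):
            return np.where(self.cum_E > 0, np.log(self.cum_E.astype(float)), np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_id": [r.cluster_id for r in self.records],
                "m": [r.m for r in self.records],
                "p": [r.p for r in self.records],
                "t": [r.t for r in self.records],
                "E": [r.E for r in self.records],
                "D": [r.D for r in self.records],
                "cum_E": self.cum_E,
                "cum_D": self.cum_D,
                "ln_cum_E": self.ln_cum_E,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


_RANK_KEYS = {
    "E": lambda r: r.E,
    "t": lambda r: r.t,
    "total": lambda r: r.m + r.p + r.t,
}


def deviation_table(table: ClusterTable, design: CrossDesign) -> list[DeviationRecord]:
    """One DeviationRecord per cluster of a (filtered) table."""
    design.validate_against(table)
    return [
        DeviationRecord(
            cluster_id=c.cluster_id,
            m=c.count(design.maternal_code),
            p=c.count(design.paternal_code),
            t=c.count(design.tetraploid_code),
        )
        for c in table.clusters
    ]


def cumulative_curve(
    records: list[DeviationRecord], rank_key: str = "E"
) -> DeviationCurve:
    """Rank records (ascending, ties by cluster_id) and accumulate E and D.

    The expected size E is the default ranking key: it is the comparison
    baseline shared by all species. Running sums are exact integer sums.
    """
    if not records:
        raise ValueError("cumulative_curve requires at least one record")
    key = _RANK_KEYS[rank_key]
    ordered = sorted(records, key=lambda r: (key(r), r.cluster_id))
    cum_E = np.cumsum([r.E for r in ordered])
    cum_D = np.cumsum([r.D for r in ordered])
    return DeviationCurve(records=ordered, cum_E=cum_E, cum_D=cum_D)


def genome_size_deviation(observed_1C: float, expected_1C: float) -> float:
    """Percent deviation of an observed 1C size from the expected parental sum."""
    if expected_1C <= 0:
        raise ValueError("expected_1C must be positive")
    return 100.0 * (observed_1C - expected_1C) / expected_1C
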