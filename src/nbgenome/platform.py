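"""Probe platform definitions for array-CGH-style copy-number profiles.

A :class:`ProbePlatform` fixes the probe grid (ordered genomic positions),
the probe chemistry (BAC clones vs. oligonucleotides — the two kinds carry
different event-qualification rules), and the reference coordinate frame
(chromosome lengths and centromere positions, GRCh37).

Sex chromosomes are excluded throughout: only the 22 autosomes are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "ProbeKind",
    "ProbePlatform",
    "GRCH37_CHROM_LENGTHS",
    "GRCH37_CENTROMERES",
    "MYCN_LOCUS",
    "AUTOSOMES",
    "make_uniform_platform",
    "default_oligo_platform",
    "default_bac_platform",
]


class ProbeKind(str, Enum):
    BAC = "BAC"
    OLIGO = "OLIGO"


AUTOSOMES: tuple[int, ...] = tuple(range(1, 23))

# GRCh37 autosome lengths (bp).
GRCH37_CHROM_LENGTHS: dict[int, int] = {
    1: 249_250_621, 2: 243_199_373, 3: 198_022_430, 4: 191_154_276,
    5: 180_915_260, 6: 171_115_067, 7: 159_138_663, 8: 146_364_022,
    9: 141_213_431, 10: 135_534_747, 11: 135_006_516, 12: 133_851_895,
    13: 115_169_878, 14: 107_349_540, 15: 102_531_392, 16: 90_354_753,
    17: 81_195_210, 18: 78_077_248, 19: 59_128_983, 20: 63_025_520,
    21: 48_129_895, 22: 51_304_566,
}

# GRCh37 centromere midpoints (bp); p-arm = [1, centromere], q-arm = rest.
GRCH37_CENTROMERES: dict[int, int] = {
    1: 125_000_000, 2: 93_300_000, 3: 91_000_000, 4: 50_400_000,
    5: 48_400_000, 6: 61_000_000, 7: 59_900_000, 8: 45_600_000,
    9: 49_000_000, 10: 40_200_000, 11: 53_700_000, 12: 35_800_000,
    13: 17_900_000, 14: 17_600_000, 15: 19_000_000, 16: 36_600_000,
    17: 24_000_000, 18: 17_200_000, 19: 26_500_000, 20: 27_500_000,
    21: 13_200_000, 22: 14_700_000,
}

# MYCN on 2p24.3 (GRCh37 chr2:16,080,683-16,087,129), padded slightly.
MYCN_LOCUS: tuple[int, int, int] = (2, 16_060_000, 16_110_000)


@dataclass(frozen=True)
class ProbePlatform:
    """An ordered autosomal probe grid with its reference coordinates.

    Parameters
    ----------
    probe_kind
        BAC or OLIGO; decides which event-qualification rule applies
        (>=3 contiguous BAC probes vs. >3 Mb of contiguous oligo probes).
    probes
        DataFrame with integer columns ``chrom`` (1..22) and ``pos`` (bp,
        1-based), sorted by (chrom, pos).
    chromosome_lengths, centromeres
        Per-chromosome length and centromere midpoint in bp.
    genome_build
        Free-text label of the coordinate frame.
    """

    probe_kind: ProbeKind
    probes: pd.DataFrame
    chromosome_lengths: dict[int, int] = field(
        default_factory=lambda: dict(GRCH37_CHROM_LENGTHS))
    centromeres: dict[int, int] = field(
        default_factory=lambda: dict(GRCH37_CENTROMERES))
    genome_build: str = "GRCh37"

    def __post_init__(self) -> None:
        p = self.probes
        if not {"chrom", "pos"}.issubset(p.columns):
            raise ValueError("probes must have columns 'chrom' and 'pos'")
        if not p[["chrom", "pos"]].equals(
                p.sort_values(["chrom", "pos"])[["chrom", "pos"]]):
            raise ValueError("probes must be sorted by (chrom, pos)")
        for chrom, grp in p.groupby("chrom"):
            if chrom not in self.chromosome_lengths:
                raise ValueError(f"no length for chromosome {chrom}")
            if chrom not in self.centromeres:
                raise ValueError(f"no centromere for chromosome {chrom}")
            if int(grp["pos"].max()) > self.chromosome_lengths[int(chrom)]:
                raise ValueError(
                    f"probe beyond end of chromosome {chrom}")

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def chrom_index(self, chrom: int) -> np.ndarray:
        """Positional indices of this chromosome's probes."""
        return np.flatnonzero(self.probes["chrom"].to_numpy() == chrom)

    def arm_interval(self, arm: str) -> tuple[int, int, int]:
        """(chrom, start, end) of a chromosome arm like '17q' or '1p'."""
        chrom, side = int(arm[:-1]), arm[-1]
        if side not in "pq":
            raise ValueError(f"unknown arm {arm!r}")
        cen = self.centromeres[chrom]
        if side == "p":
            return chrom, 1, cen
        return chrom, cen + 1, self.chromosome_lengths[chrom]


def make_uniform_platform(n_probes: int,
                          probe_kind: ProbeKind | str = ProbeKind.OLIGO,
                          ) -> ProbePlatform:
    """Evenly spaced probes over the 22 autosomes, allocated by length.

    Each autosome receives a probe count proportional to its GRCh37 length
    (at least 3), spaced uniformly from ~0.5 spacing to the chromosome end.
    """
    probe_kind = ProbeKind(probe_kind)
    total = sum(GRCH37_CHROM_LENGTHS.values())
    chroms, positions = [], []
    for c in AUTOSOMES:
        length = GRCH37_CHROM_LENGTHS[c]
        k = max(3, round(n_probes * length / total))
        pos = np.linspace(length / (2 * k), length, k, endpoint=False)
        positions.append(np.maximum(1, pos.astype(np.int64)))
        chroms.append(np.full(k, c, dtype=np.int64))
    probes = pd.DataFrame({
        "chrom": np.concatenate(chroms),
        "pos": np.concatenate(positions),
    })
    return ProbePlatform(probe_kind=probe_kind, probes=probes)


def default_oligo_platform() -> ProbePlatform:
    """10,000 oligo probes spread over the autosomes (≈290 kb spacing)."""
    return make_uniform_platform(10_000, ProbeKind.OLIGO)


def default_bac_platform() -> ProbePlatform:
    """3,000 BAC clones spread over the autosomes (≈1 Mb spacing)."""
    return make_uniform_platform(3_000, ProbeKind.BAC)
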