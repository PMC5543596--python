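"""Haplotype-scale analyses of introgressed indels.

Covers the incomplete-lineage-sorting (ILS) length test, the shared
extent of an introgressed haplotype across carriers, and perfect-LD
pairing of introgressed indels with trait-associated GWAS SNPs.

The ILS test asks whether a long shared segment between the archaic
genome and non-African haplotypes could be a remnant of ancestral
polymorphism rather than admixture.  An ILS tract around a focal point
extends independently left and right with exponential lengths of mean
L = 1/(r*t), where r is the local recombination rate per bp per
generation and t the number of generations separating the lineages; the
total tract length is therefore Gamma(shape 2, mean 2L) and the survival
probability at an observed length m is (1 + m/L) * exp(-m/L).  Old
tracts under high recombination are short, so a long observed segment
makes the ILS explanation unlikely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stratify import GenotypePanel

__all__ = [
    "ILSModel",
    "HaplotypeExtent",
    "cm_per_mb_to_rate",
    "ils_probability",
    "shared_extent",
    "perfect_ld",
    "gwas_link_report",
]


def cm_per_mb_to_rate(cm_per_mb: float) -> float:
    """Convert a recombination rate in cM/Mb to per-bp per-generation."""
    return cm_per_mb * 1e-8


@dataclass(frozen=True)
class ILSModel:
    """Parameters of the ILS tract-length test.

    r: recombination rate per bp per generation; t: branch length in
    generations separating the archaic and modern human lineages (twice
    the split time for a two-branch comparison is absorbed into the
    caller's choice of t); m: observed shared segment length in bp.
    """

    r: float
    t: float
    m: float

    def __post_init__(self) -> None:
        if self.r <= 0 or self.t <= 0 or self.m < 0:
            raise ValueError("require r > 0, t > 0, m >= 0")

    @property
    def expected_tract_length(self) -> float:
        """Mean one-sided tract extension L = 1/(r*t), in bp."""
        return 1.0 / (self.r * self.t)


def ils_probability(model: ILSModel) -> float:
    """Probability an ILS tract is at least as long as observed.

    Survival function of Gamma(shape 2, scale L) at m:
    P = (1 + m/L) * exp(-m/L).  Strictly decreasing in m and in t;
    equals 1 at m = 0.
    """
    x = model.m / model.expected_tract_length
    return float((1.0 + x) * math.exp(-x))


@dataclass(frozen=True)
class HaplotypeExtent:
    focal_id: str
    carriers: tuple[str, ...]
    shared_start: int
    shared_end: int

    @property
    def length(self) -> int:
        return self.shared_end - self.shared_start + 1


def shared_extent(
    focal_pos: int,
    positions: np.ndarray,
    dosages: np.ndarray,
    individuals: list[str],
    focal_id: str = "",
) -> HaplotypeExtent:
    """Shared extent of an introgressed haplotype across its carriers.

    ``positions`` are the sorted positions of introgressed variants in
    the window; ``dosages`` the matching (variant x individual) derived
    dosage matrix.  Carriers are individuals with at least one derived
    copy at the focal variant.  For each carrier its run is the maximal
    contiguous stretch (in the ordered variant list) of variants the
    carrier holds, containing the focal variant; the shared region is the
    intersection of all carrier runs, and the reported length spans the
    outermost introgressed variants within it (unphased genotypes stand
    in for haplotypes).
    """
    positions = np.asarray(positions)
    order = np.argsort(positions)
    positions = positions[order]
    dosages = np.asarray(dosages)[order]
    focal_idx = int(np.searchsorted(positions, focal_pos))
    if focal_idx >= len(positions) or positions[focal_idx] != focal_pos:
        raise ValueError(f"focal position {focal_pos} not among introgressed variants")
    carrier_cols = np.where(dosages[focal_idx] >= 1)[0]
    if len(carrier_cols) == 0:
        raise ValueError("focal variant has no carriers")

    lo, hi = 0, len(positions) - 1
    for col in carrier_cols:
        carried = dosages[:, col] >= 1
        i = j = focal_idx
        while i - 1 >= 0 and carried[i - 1]:
            i -= 1
        while j + 1 < len(positions) and carried[j + 1]:
            j += 1
        lo, hi = max(lo, i), min(hi, j)
    if lo > hi:  # intersection collapsed; keep the focal variant alone
        lo = hi = focal_idx
    return HaplotypeExtent(
        focal_id=focal_id,
        carriers=tuple(individuals[c] for c in carrier_cols),
        shared_start=int(positions[lo]),
        shared_end=int(positions[hi]),
    )


def perfect_ld(indel_dosages: np.ndarray, snp_dosages: np.ndarray) -> bool:
    """True iff two dosage vectors tag exactly the same carriers.

    The SNP vector is oriented to the indel's derived allele first, so a
    SNP recorded on the opposite VCF orientation (dosage 2-x) still
    counts as perfectly linked.  Vectors must cover the same individuals
    with no missing entries.
    """
    a = np.asarray(indel_dosages)
    b = np.asarray(snp_dosages)
    if a.shape != b.shape:
        raise ValueError(f"dosage vectors differ in length: {a.shape} vs {b.shape}")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("missing genotypes are not allowed in a perfect-LD test")
    return bool(np.array_equal(a, b) or np.array_equal(a, 2 - b))


def gwas_link_report(
    introgressed_indels: pd.DataFrame,
    gwas_table: pd.DataFrame,
    panel: GenotypePanel,
    indel_dosages: dict[tuple[str, int], np.ndarray],
    window: int = 1_000_000,
    p_cutoff: float = 1e-5,
    scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pair introgressed indels with perfectly linked trait-associated SNPs.

    For each introgressed indel, SNPs of the GWAS table within ``window``
    bp on the same chromosome are tested for perfect LD against the
    indel's derived-dosage vector; pairs whose association p-value is at
    most ``p_cutoff`` are reported with the EAS/EUR derived frequencies
    (and the indel's C-score when a score table is supplied).  SNPs with
    any missing genotype among the panel individuals are skipped.
    """
    snp_index = panel.variant_index()
    rows = []
    for _, ind in introgressed_indels.iterrows():
        key = (ind["chrom"], int(ind["pos"]))
        ind_dos = indel_dosages.get(key)
        if ind_dos is None or (np.asarray(ind_dos) < 0).any():
            continue
        near = gwas_table[
            (gwas_table["chrom"] == ind["chrom"])
            & (gwas_table["pos"].sub(ind["pos"]).abs() <= window)
            & (gwas_table["p"] <= p_cutoff)
        ]
        for _, snp in near.iterrows():
            idx = snp_index.get(
                (snp["chrom"], int(snp["pos"]), snp["ref"], snp["alt"])
            )
            if idx is None:
                continue
            snp_dos = panel.dosages[idx]
            if (snp_dos < 0).any():
                continue
            if perfect_ld(np.asarray(ind_dos), snp_dos):
                row = dict(
                    chrom=ind["chrom"],
                    indel_pos=int(ind["pos"]),
                    snp_pos=int(snp["pos"]),
                    rsid=snp.get("rsid", ""),
                    p=float(snp["p"]),
                    trait=snp.get("trait", ""),
                    eas_af=float(ind.get("saf_EAS", np.nan)),
                    eur_af=float(ind.get("saf_EUR", np.nan)),
                )
                if scores is not None:
                    hit = scores[
                        (scores["chrom"] == ind["chrom"])
                        & (scores["pos"] == ind["pos"])
                    ]
                    row["score"] = float(hit["score"].max()) if len(hit) else np.nan
                rows.append(row)
    cols = ["chrom", "indel_pos", "snp_pos", "rsid", "p", "trait", "eas_af", "eur_af"]
    if scores is not None:
        cols.append("score")
    return pd.DataFrame(rows, columns=cols)
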