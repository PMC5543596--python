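"""Age-stratification of human-lineage indels with a cohort and an archaic genome.

Cohort (1000-Genomes-style) indels are polarized against the seven-
outgroup consensus, merged with reference-scan calls and labeled fixed
vs polymorphic.  A Neandertal genotype track splits derived indels into
archaic-shared vs modern-human-specific, and the introgression rule —
derived allele absent in all sub-Saharan African populations, present
in Europeans or East Asians, and carried by the archaic genome — flags
putatively introgressed variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "GenotypePanel",
    "ArchaicTrack",
    "load_cohort_indels",
    "polarize_cohort_variant",
    "cohort_calls_frame",
    "merge_and_fix_status",
    "annotate_archaic",
    "detect_introgressed",
    "flag_introgressed",
    "divergence_fraction",
]

# 1000 Genomes phase 3 population codes; the five sub-Saharan African
# populations are the ones entering the introgression rule.
DEFAULT_SUPERPOPS: dict[str, str] = {
    "LWK": "AFR", "YRI": "AFR", "GWD": "AFR", "MSL": "AFR", "ESN": "AFR",
    "CEU": "EUR", "FIN": "EUR", "GBR": "EUR", "IBS": "EUR", "TSI": "EUR",
    "CDX": "EAS", "CHB": "EAS", "CHS": "EAS", "JPT": "EAS", "KHV": "EAS",
}

MISSING = -1
_VALID = frozenset("ACGT")


class PanelError(ValueError):
    pass


class PolarizationRejection(Exception):
    """Variant cannot be polarized; ``reason`` is a short code."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass
class GenotypePanel:
    """Variant x individual dosage matrix with population structure.

    ``dosages`` holds derived-agnostic ALT-allele dosages in {0,1,2} with
    -1 for missing genotypes.  Population labels map to superpopulations
    (AFR/EUR/EAS/other).
    """

    variants: pd.DataFrame  # columns chrom, pos, ref, alt
    dosages: np.ndarray  # (n_variants, n_individuals), int8
    individuals: list[str]
    pop_of: dict[str, str]
    superpop_of: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SUPERPOPS))

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.variants), len(self.individuals)):
            raise PanelError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.variants)} variants x {len(self.individuals)} individuals"
            )

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.pop_of.values()))

    def pop_columns(self, pop: str) -> np.ndarray:
        return np.array(
            [k for k, ind in enumerate(self.individuals) if self.pop_of[ind] == pop],
            dtype=int,
        )

    def alt_counts(self, var_idx: int) -> dict[str, tuple[int, int]]:
        """Per population: (ALT allele count, called chromosome count)."""
        row = self.dosages[var_idx]
        out = {}
        for pop in self.populations:
            cols = self.pop_columns(pop)
            d = row[cols]
            called = d[d != MISSING]
            out[pop] = (int(called.sum()), 2 * len(called))
        return out

    def variant_index(self) -> dict[tuple, int]:
        return {
            (r.chrom, int(r.pos), r.ref, r.alt): i
            for i, r in enumerate(self.variants.itertuples(index=False))
        }


def _is_symbolic(alt: str) -> bool:
    return alt.startswith("<") or any(ch in alt for ch in "[]*.")


def load_cohort_indels(
    vcf_path: str,
    pops: dict[str, str] | pd.DataFrame,
    superpops: dict[str, str] | None = None,
) -> GenotypePanel:
    """Read biallelic 1-5 bp indels from a cohort VCF into a panel.

    SNPs, symbolic alleles (``<CN0>`` copy-number records and the like),
    multiallelic sites (more than one derived variant) and length
    differences outside 1-5 bp are excluded.  Every VCF sample must
    appear in the individual-to-population table.
    """
    if isinstance(pops, pd.DataFrame):
        pops = dict(zip(pops.iloc[:, 0], pops.iloc[:, 1]))
    vcf = VCF(vcf_path, gts012=True)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in pops]
    if unknown:
        raise PanelError(f"individuals absent from population table: {unknown}")

    rows = []
    dosage_rows = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue  # multiallelic: more than one derived variant
        ref, alt = v.REF, v.ALT[0]
        if _is_symbolic(alt):
            continue
        if not (set(ref.upper()) <= _VALID and set(alt.upper()) <= _VALID):
            continue
        diff = abs(len(alt) - len(ref))
        if not (1 <= diff <= 5):
            continue
        gt = v.gt_types.astype(np.int8)  # 0/1/2 dosage, 3 = unknown
        gt[gt == 3] = MISSING
        rows.append((v.CHROM, v.POS, ref, alt))
        dosage_rows.append(gt)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosages = (
        np.vstack(dosage_rows) if dosage_rows else np.empty((0, len(samples)), np.int8)
    )
    return GenotypePanel(
        variants=variants,
        dosages=dosages,
        individuals=samples,
        pop_of={s: pops[s] for s in samples},
        superpop_of=dict(superpops or DEFAULT_SUPERPOPS),
    )


def _split_anchor(ref: str, alt: str) -> tuple[str, str, str]:
    """Return (event_of_alt, deleted_or_inserted_seq, longer_suffix check).

    Requires the anchored prefix representation (the shorter allele is a
    prefix of the longer); raises PolarizationRejection otherwise.
    """
    if len(ref) == len(alt):
        raise PolarizationRejection("not_an_indel", f"{ref}>{alt}")
    short, long_ = (ref, alt) if len(ref) < len(alt) else (alt, ref)
    if not long_.startswith(short):
        raise PolarizationRejection("unpolarizable", "alleles not prefix-anchored")
    seq = long_[len(short):]
    event_of_alt = "insertion" if len(alt) > len(ref) else "deletion"
    return event_of_alt, seq, short


def polarize_cohort_variant(
    variant: tuple[str, int, str, str],
    outgroup_allele: str,
    panel: GenotypePanel,
    var_idx: int | None = None,
):
    """Polarize one cohort indel against the 7-outgroup consensus allele.

    ``outgroup_allele`` is the (anchored) state all seven outgroups carry
    at the site; the matching VCF allele becomes ancestral.  Returns a
    dict record with unanchored ancestral/derived alleles, the event type
    of the *derived* allele and per-population derived allele frequencies.
    Raises :class:`PolarizationRejection` (reasons ``outgroup_disagreement``
    handled upstream, ``not_aligned``, ``unpolarizable``).
    """
    chrom, pos, ref, alt = variant
    if outgroup_allele is None:
        raise PolarizationRejection("not_aligned", f"{chrom}:{pos}")
    event_of_alt, seq, _ = _split_anchor(ref, alt)
    og = outgroup_allele.upper()
    if og == ref.upper():
        ancestral, derived = ref, alt
        derived_is_alt = True
        event = event_of_alt
    elif og == alt.upper():
        ancestral, derived = alt, ref
        derived_is_alt = False
        event = "deletion" if event_of_alt == "insertion" else "insertion"
    else:
        raise PolarizationRejection(
            "unpolarizable", f"outgroup {og} matches neither {ref} nor {alt}"
        )

    if var_idx is None:
        var_idx = panel.variant_index()[(chrom, pos, ref, alt)]
    counts = panel.alt_counts(var_idx)
    pop_daf: dict[str, float] = {}
    pop_counts: dict[str, tuple[int, int]] = {}
    for pop, (ac, an) in counts.items():
        dc = ac if derived_is_alt else an - ac
        pop_daf[pop] = dc / an if an else float("nan")
        pop_counts[pop] = (dc, an)

    anc_un, der_un = ("", seq) if event == "insertion" else (seq, "")
    rec = {
        "chrom": chrom,
        "pos": pos,
        "length": len(seq),
        "event": event,
        "ancestral": anc_un,
        "derived": der_un,
        "origin": "cohort_vcf",
        "fixation": "polymorphic",
        "derived_is_alt": derived_is_alt,
        "var_idx": var_idx,
    }
    for pop, f in pop_daf.items():
        rec[f"daf_{pop}"] = f
    # superpopulation frequencies pooled over member populations
    sp_counts: dict[str, list[int]] = {}
    for pop, (dc, an) in pop_counts.items():
        sp = panel.superpop_of.get(pop, "other")
        sp_counts.setdefault(sp, [0, 0])
        sp_counts[sp][0] += dc
        sp_counts[sp][1] += an
    for sp, (dc, an) in sp_counts.items():
        rec[f"saf_{sp}"] = dc / an if an else float("nan")
    return rec


def cohort_calls_frame(
    panel: GenotypePanel, outgroup_alleles: dict[tuple[str, int], str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Polarize every panel variant; returns (calls, rejections) frames.

    ``outgroup_alleles`` maps (chrom, pos) to the anchored consensus state
    of the seven outgroups; sites absent from the mapping are rejected as
    ``not_aligned``.
    """
    recs, rejects = [], []
    for i, r in enumerate(panel.variants.itertuples(index=False)):
        variant = (r.chrom, int(r.pos), r.ref, r.alt)
        try:
            recs.append(
                polarize_cohort_variant(
                    variant, outgroup_alleles.get((r.chrom, int(r.pos))), panel, i
                )
            )
        except PolarizationRejection as exc:
            rejects.append((r.chrom, int(r.pos), exc.reason))
    calls = pd.DataFrame(recs)
    rej = pd.DataFrame(rejects, columns=["chrom", "pos", "reason"])
    return calls, rej


def merge_and_fix_status(
    reference_calls: pd.DataFrame, cohort_calls: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge reference-scan and cohort calls and assign fixation status.

    Reference-scan calls with no cohort record at the position are fixed
    (all outgroups differ, nobody segregates the ancestral state); when a
    cohort record exists with compatible alleles the cohort record wins
    as polymorphic.  Cohort variants at derived frequency 1.0 in every
    population are promoted to fixed.  Position collisions with
    incompatible alleles drop both records (logged).
    """
    dropped = []
    cohort = cohort_calls.copy()
    daf_cols = [c for c in cohort.columns if c.startswith("daf_")]
    if not cohort.empty:
        all_one = (cohort[daf_cols].fillna(1.0) >= 1.0).all(axis=1)
        cohort.loc[all_one, "fixation"] = "fixed"
    cohort_by_pos = (
        {
            (r["chrom"], r["pos"]): r
            for _, r in cohort.iterrows()
        }
        if not cohort.empty
        else {}
    )
    out_rows = []
    claimed = set()
    for _, r in reference_calls.iterrows():
        key = (r["chrom"], r["pos"])
        if key in cohort_by_pos:
            c = cohort_by_pos[key]
            if (c["ancestral"], c["derived"]) == (r["ancestral"], r["derived"]):
                claimed.add(key)  # cohort record wins
            else:
                dropped.append((r["chrom"], r["pos"], "incompatible_alleles"))
                claimed.add(key)
                cohort_by_pos.pop(key)
        else:
            rec = r.to_dict()
            rec["fixation"] = "fixed"
            out_rows.append(rec)
    merged = pd.DataFrame(out_rows)
    keep_cohort = (
        cohort[[(r["chrom"], r["pos"]) in cohort_by_pos for _, r in cohort.iterrows()]]
        if not cohort.empty
        else cohort
    )
    merged = pd.concat([merged, keep_cohort], ignore_index=True)
    if not merged.empty:
        merged = merged.sort_values(["chrom", "pos"]).reset_index(drop=True)
    drop_df = pd.DataFrame(dropped, columns=["chrom", "pos", "reason"])
    return merged, drop_df


@dataclass
class ArchaicTrack:
    """Archaic (Neandertal) genotypes with a coverage mask.

    A site is covered iff it appears with a non-missing genotype; the
    stored dosage counts the ALT allele of the archaic VCF record.
    """

    records: dict[tuple[str, int], tuple[str, str, int]]  # (ref, alt, alt_dosage)

    @classmethod
    def from_vcf(cls, path: str) -> "ArchaicTrack":
        vcf = VCF(path, gts012=True)
        records = {}
        for v in vcf:
            if len(v.ALT) > 1:
                continue
            gt = int(v.gt_types[0])
            if gt == 3:
                continue  # missing genotype: site stays uncovered
            alt = v.ALT[0] if v.ALT else v.REF
            records[(v.CHROM, v.POS)] = (v.REF, alt, gt)
        return cls(records)

    def derived_dosage(
        self, chrom: str, pos: int, event: str, ancestral: str, derived: str
    ) -> int | None:
        """Archaic dosage of the derived allele, or None if uncovered.

        ``ancestral``/``derived`` are the unanchored event alleles; the
        archaic record's REF/ALT pair is reduced to the same representation
        before matching.  Records whose alleles do not describe the same
        event are treated as uncovered.
        """
        rec = self.records.get((chrom, pos))
        if rec is None:
            return None
        ref, alt, alt_dosage = rec
        if len(ref) == len(alt):
            return None
        try:
            event_of_alt, seq, _ = _split_anchor(ref, alt)
        except PolarizationRejection:
            return None
        indel_seq = ancestral if event == "deletion" else derived
        if seq.upper() != indel_seq.upper():
            return None
        derived_is_alt = event_of_alt == event
        return alt_dosage if derived_is_alt else 2 - alt_dosage


def annotate_archaic(indels: pd.DataFrame, archaic: ArchaicTrack) -> pd.DataFrame:
    """Label each indel archaic_shared / modern_specific / uncovered.

    Sharing requires at least one archaic copy of the derived allele
    (heterozygous counts as shared); uncovered sites carry no evidence
    and are excluded from shared-vs-specific contrasts downstream.
    """
    out = indels.copy()
    labels = []
    for _, r in out.iterrows():
        d = archaic.derived_dosage(
            r["chrom"], r["pos"], r["event"], r["ancestral"], r["derived"]
        )
        if d is None:
            labels.append("uncovered")
        elif d >= 1:
            labels.append("archaic_shared")
        else:
            labels.append("modern_specific")
    out["sharing"] = labels
    return out


def detect_introgressed(
    indel: pd.Series | dict,
    panel: GenotypePanel,
    archaic: ArchaicTrack,
    african_pops: list[str] | None = None,
) -> bool:
    """Apply the introgression rule to one polymorphic archaic-shared indel.

    True iff the derived allele is absent (frequency exactly 0) from every
    configured sub-Saharan African population, present in the EUR or EAS
    superpopulation, and carried by the archaic genome.
    """
    r = dict(indel)
    if r.get("fixation") != "polymorphic" or r.get("sharing") != "archaic_shared":
        return False
    if african_pops is None:
        african_pops = [
            p for p in panel.populations if panel.superpop_of.get(p) == "AFR"
        ]
    for pop in african_pops:
        f = r.get(f"daf_{pop}")
        if f is None or not np.isfinite(f) or f > 0:
            return False
    eur = r.get("saf_EUR", 0.0) or 0.0
    eas = r.get("saf_EAS", 0.0) or 0.0
    if not (eur > 0 or eas > 0):
        return False
    d = archaic.derived_dosage(
        r["chrom"], r["pos"], r["event"], r["ancestral"], r["derived"]
    )
    return bool(d is not None and d >= 1)


def flag_introgressed(
    indels: pd.DataFrame,
    panel: GenotypePanel,
    archaic: ArchaicTrack,
    african_pops: list[str] | None = None,
) -> pd.DataFrame:
    """Vectorized wrapper adding a boolean ``introgressed`` column."""
    out = indels.copy()
    out["introgressed"] = [
        detect_introgressed(r, panel, archaic, african_pops)
        for _, r in out.iterrows()
    ]
    return out


def divergence_fraction(n_modern_specific: int, n_shared: int) -> float:
    """Percent divergence accumulated since the archaic split.

    The fraction of derived indels not shared with the archaic genome,
    relative to all derived indels since the common ancestor with
    chimpanzee, expressed in percent.
    """
    if n_modern_specific < 0 or n_shared < 0:
        raise ValueError("counts must be non-negative")
    total = n_modern_specific + n_shared
    if total == 0:
        raise ValueError("divergence undefined for zero total")
    return 100.0 * n_modern_specific / total
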