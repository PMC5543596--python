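"""Desk-scale synthetic data with the statistical structure the pipeline assumes.

Three generators cover the pipeline's inputs without any downloads:

* :func:`simulate_alignment` emits an 8-species MAF with planted 1-5 bp
  human-lineage indels (deletions arising at twice the insertion rate, as
  observed for primate genomes) plus optional homoplasic events, and the
  matching truth table.
* :func:`simulate_cohort` emits a three-superpopulation cohort VCF
  (AFR/EUR/EAS), an archaic genotype VCF with a coverage mask, planted
  low-frequency introgressed haplotypes, a population table, an
  outgroup-consensus table and the truth table.
* :func:`simulate_mk_counts` draws MK-style 2x2 tables under a chosen
  deletion:insertion mutation-rate ratio and fixation-probability ratio.

All generators are deterministic given the seed (byte-identical files).
Sites outside planted haplotypes are independent (no background linkage);
this is adequate for rule-based detection but is not a coalescent model.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .polarize import SpeciesConfig
from .selection import ContingencyTable

__all__ = [
    "SimConfig",
    "simulate_alignment",
    "simulate_cohort",
    "simulate_mk_counts",
]

BASES = np.array(list("ACGT"))

# default population layout: two 1000G-style populations per superpopulation
DEFAULT_POPS = {
    "YRI": "AFR", "LWK": "AFR",
    "CEU": "EUR", "TSI": "EUR",
    "CHB": "EAS", "JPT": "EAS",
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generators.

    Rates follow the observed genome-wide pattern of deletions arising at
    roughly twice the insertion rate; planted introgressed haplotypes
    target the mean derived frequencies measured for introgressed
    variants in Europeans (0.027) and East Asians (0.048).
    """

    seed: int = 0
    # alignment
    n_blocks: int = 5
    block_length: int = 5000
    deletion_rate: float = 0.002  # per ancestral bp on the human lineage
    insertion_rate: float = 0.001
    n_events: int | None = None  # override rates with an exact event count
    homoplasy_rate: float = 0.0
    substitution_rate: float = 0.005  # outgroup noise away from events
    # cohort
    n_individuals: int = 100  # per superpopulation
    site_count: int = 400
    p_shared: float = 0.3  # background sites whose derived allele is archaic-shared
    p_fixed: float = 0.02
    archaic_coverage: float = 1.0
    n_introgressed_haplotypes: int = 5
    haplotype_length: int = 200_000
    variant_spacing: int = 2000  # mean spacing of introgressed variants, bp
    eur_target_af: float = 0.027
    eas_target_af: float = 0.048
    pops: dict = field(default_factory=lambda: dict(DEFAULT_POPS))

    def __post_init__(self) -> None:
        for p in (
            self.deletion_rate, self.insertion_rate, self.homoplasy_rate,
            self.substitution_rate, self.p_shared, self.p_fixed,
            self.archaic_coverage, self.eur_target_af, self.eas_target_af,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        total_rate = self.deletion_rate + self.insertion_rate
        if total_rate * 12 > 0.9:  # events need ~12 bp separation to pack
            raise ValueError("indel rates imply overlapping events")


# ---------------------------------------------------------------------------
# alignment simulator


def _plan_events(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[int, int, str, int]]:
    """Choose (block, anc_pos, event, length) with a 12 bp separation guard."""
    guard = 12
    spots: list[tuple[int, int]] = []
    for b in range(cfg.n_blocks):
        lo, hi = guard, cfg.block_length - guard
        spots.extend((b, p) for p in range(lo, hi))
    if cfg.n_events is not None:
        n = cfg.n_events
        p_del = cfg.deletion_rate / (cfg.deletion_rate + cfg.insertion_rate)
    else:
        total = cfg.n_blocks * cfg.block_length
        n = rng.binomial(total, cfg.deletion_rate + cfg.insertion_rate)
        p_del = cfg.deletion_rate / (cfg.deletion_rate + cfg.insertion_rate)
    # rejection-sample well-separated positions
    chosen: list[tuple[int, int]] = []
    occupied: dict[int, list[int]] = {b: [] for b in range(cfg.n_blocks)}
    idx = rng.permutation(len(spots))
    for k in idx:
        b, p = spots[k]
        if all(abs(p - q) >= guard for q in occupied[b]):
            occupied[b].append(p)
            chosen.append((b, p))
            if len(chosen) == n:
                break
    if len(chosen) < n:
        raise ValueError("cannot place the requested events with the separation guard")
    events = []
    for b, p in sorted(chosen):
        ev = "deletion" if rng.random() < p_del else "insertion"
        length = int(rng.integers(1, 6))
        events.append((b, p, ev, length))
    return events


def simulate_alignment(
    cfg: SimConfig, outdir: str, species: SpeciesConfig | None = None
) -> tuple[str, pd.DataFrame]:
    """Write an 8-species MAF with planted indels; return (maf_path, truth).

    Planted events are left-normalized at generation time (the base
    before each event is forced to differ from the event's last base) so
    truth coordinates match the pipeline's canonical gap placement.
    Homoplasic events copy the human state into one random outgroup and
    are flagged in the truth table.
    """
    species = species or SpeciesConfig()
    rng = np.random.default_rng(cfg.seed)
    os.makedirs(outdir, exist_ok=True)
    events = _plan_events(cfg, rng)
    by_block: dict[int, dict[int, tuple]] = {}
    for b, p, ev, length in events:
        by_block.setdefault(b, {})[p] = (ev, length)

    truth_rows = []
    human_start = 0
    species_starts = {sp: 0 for sp in species.outgroups}
    all_rows: list[dict] = []

    for b in range(cfg.n_blocks):
        anc = rng.choice(BASES, size=cfg.block_length)
        block_events = by_block.get(b, {})
        # enforce left-normalized placement and pick event payloads
        payload: dict[int, tuple[str, int, str, str | None]] = {}
        for p, (ev, length) in sorted(block_events.items()):
            hom_sp = (
                species.outgroups[int(rng.integers(0, 7))]
                if rng.random() < cfg.homoplasy_rate
                else None
            )
            if ev == "deletion":
                # base before event must differ from its last base
                if anc[p - 1] == anc[p + length - 1]:
                    anc[p - 1] = rng.choice(BASES[BASES != anc[p + length - 1]])
                seq = "".join(anc[p : p + length])
            else:
                # the gap run sits right of the anchor base anc[p]; the last
                # inserted base must differ from it or left-normalization
                # would slide the event one column left of the planted pos
                seq = "".join(rng.choice(BASES, size=length))
                if seq[-1] == anc[p]:
                    alt = [ch for ch in "ACGT" if ch != anc[p]]
                    seq = seq[:-1] + str(rng.choice(alt))
            payload[p] = (ev, length, seq, hom_sp)

        cols_h: list[str] = []
        cols_o: dict[str, list[str]] = {sp: [] for sp in species.outgroups}
        event_cols: set[int] = set()
        emitted = 0
        i = 0
        while i < cfg.block_length:
            ev_here = payload.get(i)
            if ev_here and ev_here[0] == "deletion":
                ev, length, seq, hom_sp = ev_here
                truth_rows.append(
                    dict(
                        chrom="chr1", pos=human_start + emitted, length=length,
                        event="deletion", ancestral=seq, derived="",
                        homoplasy=hom_sp is not None,
                    )
                )
                for k in range(length):
                    event_cols.add(len(cols_h))
                    cols_h.append("-")
                    for sp in species.outgroups:
                        cols_o[sp].append("-" if sp == hom_sp else seq[k])
                i += length
                continue
            base = str(anc[i])
            cols_h.append(base)
            for sp in species.outgroups:
                cols_o[sp].append(base)
            emitted += 1
            if ev_here and ev_here[0] == "insertion":
                ev, length, seq, hom_sp = ev_here
                truth_rows.append(
                    dict(
                        chrom="chr1", pos=human_start + emitted, length=length,
                        event="insertion", ancestral="", derived=seq,
                        homoplasy=hom_sp is not None,
                    )
                )
                for ch in seq:
                    event_cols.add(len(cols_h))
                    cols_h.append(ch)
                    emitted += 1
                    for sp in species.outgroups:
                        cols_o[sp].append(ch if sp == hom_sp else "-")
            i += 1

        # outgroup substitution noise away from event columns
        protected = set()
        for c in event_cols:
            protected.update((c - 1, c, c + 1))
        ncols = len(cols_h)
        for sp in species.outgroups:
            noise = rng.random(ncols) < cfg.substitution_rate
            for c in np.nonzero(noise)[0]:
                if int(c) in protected or cols_o[sp][c] == "-":
                    continue
                cur = cols_o[sp][c]
                cols_o[sp][c] = str(rng.choice(BASES[BASES != cur]))

        human_gapped = "".join(cols_h)
        human_size = sum(ch != "-" for ch in human_gapped)
        rows = [dict(sp=species.human, start=human_start, text=human_gapped)]
        for sp in species.outgroups:
            text = "".join(cols_o[sp])
            rows.append(dict(sp=sp, start=species_starts[sp], text=text))
            species_starts[sp] += sum(ch != "-" for ch in text)
        all_rows.append(rows)
        human_start += human_size

    src_sizes = {species.human: human_start}
    src_sizes.update(species_starts)
    lines = ["##maf version=1 scoring=none", ""]
    for rows in all_rows:
        lines.append("a score=0.0")
        for r in rows:
            sp = r["sp"]
            size = sum(ch != "-" for ch in r["text"])
            lines.append(
                f"s {sp}.chr1 {r['start']} {size} + {src_sizes[sp]} {r['text']}"
            )
        lines.append("")
    maf_path = os.path.join(outdir, "alignment.maf")
    with open(maf_path, "w") as fh:
        fh.write("\n".join(lines))

    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "length", "event", "ancestral", "derived", "homoplasy"],
    ).sort_values(["chrom", "pos"]).reset_index(drop=True)
    truth.to_csv(os.path.join(outdir, "alignment_truth.tsv"), sep="\t", index=False)
    return maf_path, truth


# ---------------------------------------------------------------------------
# cohort simulator


def _neutral_daf(rng: np.random.Generator, n_chrom: int) -> float:
    """Draw a derived allele frequency from a discretized 1/x spectrum."""
    k = np.arange(1, n_chrom)
    w = 1.0 / k
    return float(rng.choice(k, p=w / w.sum()) / n_chrom)


def _site_alleles(rng: np.random.Generator) -> tuple[str, int, str, str]:
    """Random event: (event_of_derived, length, ancestral_anchored, derived_anchored)."""
    length = int(rng.integers(1, 6))
    anchor = str(rng.choice(BASES))
    seq = "".join(rng.choice(BASES, size=length))
    if rng.random() < 2.0 / 3.0:  # deletions arise at twice the insertion rate
        return "deletion", length, anchor + seq, anchor
    return "insertion", length, anchor, anchor + seq


def simulate_cohort(cfg: SimConfig, outdir: str) -> dict[str, object]:
    """Write cohort + archaic VCFs, pops/outgroup tables and the truth table.

    Planted introgressed haplotypes are contiguous runs of derived
    variants carried by the archaic genome and a small set of EUR/EAS
    carrier chromosomes (targeting the configured mean frequencies),
    absent from every African individual.  Background sites are
    independent; archaic-shared background sites are forced to carry at
    least one African derived allele so the introgression rule's planted
    truth is exact by construction.

    Returns a dict with paths (cohort_vcf, archaic_vcf, pops, outgroups,
    truth) and the truth DataFrame.
    """
    rng = np.random.default_rng(cfg.seed)
    os.makedirs(outdir, exist_ok=True)

    pops = list(cfg.pops)
    superpop = dict(cfg.pops)
    individuals: list[str] = []
    pop_of: dict[str, str] = {}
    per_pop = {}
    for sp in ("AFR", "EUR", "EAS"):
        members = [p for p in pops if superpop[p] == sp]
        base, extra = divmod(cfg.n_individuals, len(members))
        for j, p in enumerate(members):
            per_pop[p] = base + (1 if j < extra else 0)
    for p in pops:
        for k in range(per_pop[p]):
            name = f"{p}{k:03d}"
            individuals.append(name)
            pop_of[name] = p
    n_ind = len(individuals)
    cols = {sp: [i for i, ind in enumerate(individuals) if superpop[pop_of[ind]] == sp]
            for sp in ("AFR", "EUR", "EAS")}

    # --- site positions
    sites = []  # dicts with pos and roles
    bg_span = cfg.site_count * 1000
    bg_pos = np.sort(
        rng.choice(np.arange(100, bg_span, 20), size=cfg.site_count, replace=False)
    )
    hap_start0 = bg_span + 100_000
    hap_regions = []
    for h in range(cfg.n_introgressed_haplotypes):
        start = hap_start0 + h * (cfg.haplotype_length + 100_000)
        # jittered grid: spacing is uniform around its mean and the first and
        # last variants sit within ~spacing/2 of the haplotype ends, so the
        # recovered shared extent underestimates the planted length by about
        # half a spacing per side
        n_var = max(2, int(round(cfg.haplotype_length / cfg.variant_spacing)))
        centers = np.linspace(
            cfg.variant_spacing / 4,
            cfg.haplotype_length - cfg.variant_spacing / 4,
            n_var,
        )
        jitter = rng.uniform(-cfg.variant_spacing / 4, cfg.variant_spacing / 4, n_var)
        offsets = np.unique((centers + jitter).astype(int))
        offsets = offsets[(offsets >= 1) & (offsets < cfg.haplotype_length)]
        hap_regions.append((h, start, start + offsets))

    rows = []  # per-site record dicts
    for pos in bg_pos:
        event, length, anc, der = _site_alleles(rng)
        dosage = np.zeros(n_ind, dtype=np.int8)
        fixed = rng.random() < cfg.p_fixed
        if fixed:
            dosage[:] = 2
            shared = True  # fixed derived alleles predate the split
            covered = rng.random() < cfg.archaic_coverage
            arch = 2
        else:
            f = _neutral_daf(rng, 2 * n_ind)
            dosage = rng.binomial(2, f, size=n_ind).astype(np.int8)
            if dosage.sum() == 0:
                dosage[int(rng.integers(0, n_ind))] = 1
            if dosage.sum() == 2 * n_ind:
                dosage[int(rng.integers(0, n_ind))] = 1
            shared = rng.random() < cfg.p_shared
            covered = rng.random() < cfg.archaic_coverage
            if shared:
                arch = int(rng.integers(1, 3))
                if dosage[cols["AFR"]].sum() == 0:
                    dosage[int(rng.choice(cols["AFR"]))] = 1
            else:
                arch = 0
        rows.append(
            dict(
                pos=int(pos), event=event, length=length, anc=anc, der=der,
                dosage=dosage, arch=arch, covered=covered, hap=-1,
                fixed=bool(fixed or dosage.sum() == 2 * n_ind),
            )
        )

    for h, start, positions in hap_regions:
        non_afr = cols["EUR"] + cols["EAS"]
        while True:  # guarantee at least one non-African carrier chromosome
            carrier = np.zeros(n_ind, dtype=np.int8)
            for i in cols["EUR"]:
                carrier[i] = rng.binomial(2, cfg.eur_target_af)
            for i in cols["EAS"]:
                carrier[i] = rng.binomial(2, cfg.eas_target_af)
            if carrier[non_afr].sum() > 0:
                break
        for pos in positions:
            event, length, anc, der = _site_alleles(rng)
            rows.append(
                dict(
                    pos=int(pos), event=event, length=length, anc=anc, der=der,
                    dosage=carrier.copy(), arch=2, covered=True, hap=h,
                    fixed=False,
                )
            )

    rows.sort(key=lambda r: r["pos"])

    # --- VCF orientation: REF is the human reference allele; flip half the
    # sites so the derived allele is sometimes REF (polarity-flip coverage)
    truth_rows = []
    vcf_lines = []
    arch_lines = []
    outgroup_rows = []
    for r in rows:
        flip = bool(rng.random() < 0.5) and not r["fixed"]
        if flip:
            ref, alt = r["der"], r["anc"]
            alt_is_derived = False
        else:
            ref, alt = r["anc"], r["der"]
            alt_is_derived = True
        dos = r["dosage"] if alt_is_derived else (2 - r["dosage"]).astype(np.int8)
        gts = []
        for d in dos:
            gts.append("0/0" if d == 0 else ("0/1" if d == 1 else "1/1"))
        vcf_lines.append(
            f"chr1\t{r['pos']}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
        arch_alt_dos = r["arch"] if alt_is_derived else 2 - r["arch"]
        if r["covered"]:
            agt = "0/0" if arch_alt_dos == 0 else ("0/1" if arch_alt_dos == 1 else "1/1")
            arch_lines.append(f"chr1\t{r['pos']}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{agt}")
        outgroup_rows.append(dict(chrom="chr1", pos=r["pos"], outgroup_allele=r["anc"]))

        if r["fixed"]:
            sharing = (
                ("archaic_shared" if r["arch"] >= 1 else "modern_specific")
                if r["covered"] else "uncovered"
            )
        elif not r["covered"]:
            sharing = "uncovered"
        else:
            sharing = "archaic_shared" if r["arch"] >= 1 else "modern_specific"
        dafs = {}
        for sp in ("AFR", "EUR", "EAS"):
            sub = r["dosage"][cols[sp]]
            dafs[f"daf_{sp}"] = float(sub.sum() / (2 * len(sub)))
        truth_rows.append(
            dict(
                chrom="chr1", pos=r["pos"], ref=ref, alt=alt,
                ancestral_state=r["anc"], event=r["event"], length=r["length"],
                fixation="fixed" if r["fixed"] else "polymorphic",
                sharing=sharing,
                introgressed=r["hap"] >= 0, hap=r["hap"], **dafs,
            )
        )

    header = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(individuals),
    ]
    cohort_vcf = os.path.join(outdir, "cohort.vcf")
    with open(cohort_vcf, "w") as fh:
        fh.write("\n".join(header + vcf_lines) + "\n")
    arch_header = header[:-1] + [
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tAltai"
    ]
    archaic_vcf = os.path.join(outdir, "archaic.vcf")
    with open(archaic_vcf, "w") as fh:
        fh.write("\n".join(arch_header + arch_lines) + "\n")

    pops_path = os.path.join(outdir, "pops.tsv")
    pd.DataFrame(
        {"individual": individuals, "population": [pop_of[i] for i in individuals]}
    ).to_csv(pops_path, sep="\t", index=False, header=False)
    outgroups_path = os.path.join(outdir, "outgroups.tsv")
    pd.DataFrame(outgroup_rows).to_csv(outgroups_path, sep="\t", index=False)
    truth = pd.DataFrame(truth_rows)
    truth_path = os.path.join(outdir, "cohort_truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)
    return dict(
        cohort_vcf=cohort_vcf,
        archaic_vcf=archaic_vcf,
        pops=pops_path,
        outgroups=outgroups_path,
        truth_path=truth_path,
        truth=truth,
        superpops=superpop,
    )


# ---------------------------------------------------------------------------
# MK table simulator


def simulate_mk_counts(
    rho: float,
    sel_diff: float,
    n_fixed: int,
    n_poly: int,
    seed: int | np.random.Generator = 0,
) -> ContingencyTable:
    """Draw one MK-style 2x2 under given rate and fixation-probability ratios.

    Polymorphic deletion:insertion proportions are rho : 1; fixed
    proportions rho * sel_diff : 1 (sel_diff < 1 means deletions fix less
    often).  Under sel_diff = 1 the table is neutral and the Fisher test
    should reject at its nominal rate.
    """
    if rho <= 0 or sel_diff <= 0:
        raise ValueError("rho and sel_diff must be positive")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    p_fix = rho * sel_diff / (rho * sel_diff + 1.0)
    p_poly = rho / (rho + 1.0)
    a = int(rng.binomial(n_fixed, p_fix)) if n_fixed else 0
    c = int(rng.binomial(n_poly, p_poly)) if n_poly else 0
    return ContingencyTable(
        a=a, b=n_fixed - a, c=c, d=n_poly - c, row_labels=("fixed", "polymorphic")
    )
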