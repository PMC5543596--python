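import numpy as np
import pandas as pd
import pytest

from indelstrata import (
    ArchaicTrack,
    SimConfig,
    SpeciesConfig,
    annotate_archaic,
    cohort_calls_frame,
    flag_introgressed,
    load_cohort_indels,
    merge_and_fix_status,
    simulate_alignment,
    simulate_cohort,
)
from indelstrata.polarize import AlignmentBlock

SPECIES = SpeciesConfig()


def make_block(human: str, outgroups, ref_start: int = 10, chrom: str = "chr1"):
    """Build an AlignmentBlock from a human row and 7 outgroup rows.

    ``outgroups`` may be a single string (applied to all seven) or a list.
    """
    if isinstance(outgroups, str):
        outgroups = [outgroups] * 7
    seqs = {SPECIES.human: human}
    seqs.update(dict(zip(SPECIES.outgroups, outgroups)))
    return AlignmentBlock(
        ref_chrom=chrom,
        ref_start=ref_start,
        seqs=seqs,
        species_order=list(SPECIES.all_species),
    )


def write_vcf(path, samples, records):
    """Write a minimal VCF: records are (chrom, pos, ref, alts, genotypes)."""
    header = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    lines = []
    for chrom, pos, ref, alts, gts in records:
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alts}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(header + lines) + "\n")
    return str(path)


@pytest.fixture(scope="session")
def planted_alignment(tmp_path_factory):
    """Alignment with 500 planted events, 10% homoplasy (fixed seed)."""
    outdir = tmp_path_factory.mktemp("aln")
    cfg = SimConfig(seed=20170804, n_events=500, homoplasy_rate=0.1)
    maf_path, truth = simulate_alignment(cfg, str(outdir))
    return maf_path, truth


@pytest.fixture(scope="session")
def cohort_bundle(tmp_path_factory):
    """Cohort of 300 individuals with 5 planted introgressed haplotypes,
    run through the full stratification pipeline once."""
    outdir = tmp_path_factory.mktemp("cohort")
    cfg = SimConfig(
        seed=20170804,
        site_count=400,
        n_individuals=100,
        n_introgressed_haplotypes=5,
        archaic_coverage=0.8,
    )
    out = simulate_cohort(cfg, str(outdir))
    pops = pd.read_csv(out["pops"], sep="\t", header=None)
    panel = load_cohort_indels(out["cohort_vcf"], pops)
    og = pd.read_csv(out["outgroups"], sep="\t")
    og_map = {(r.chrom, int(r.pos)): r.outgroup_allele for r in og.itertuples()}
    calls, rejections = cohort_calls_frame(panel, og_map)
    empty_ref = pd.DataFrame(
        columns=["chrom", "pos", "length", "event", "ancestral", "derived", "origin"]
    )
    merged, _ = merge_and_fix_status(empty_ref, calls)
    track = ArchaicTrack.from_vcf(out["archaic_vcf"])
    merged = annotate_archaic(merged, track)
    merged = flag_introgressed(merged, panel, track)
    return dict(sim=out, panel=panel, track=track, stratified=merged, truth=out["truth"])
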