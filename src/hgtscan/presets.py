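"""Packaged study-condition configurations for validation runs.

Each preset pins the cohort structure of the study system — 47 tumors split
7 (carrier clade) / 40, purity 0.7–0.95, mean depth 77, clades split 2,000
years ago, transfer at 2,000 years, per-copy substitution rate 3.435e-7 per
site per year — and scales the remaining free quantities (genome size, panel
density, CpG density) to what the specific validation needs, so that each
check runs at desk scale with calibrated statistical power.
"""

from __future__ import annotations

from .simcohort import SimConfig

#: 5.5-Mb single-block transfer used by the screen-recovery validation
SCREEN_BLOCK = ("chr7", 2_000_000, 7_500_000, "+")


def screen_validation_config(seed: int) -> SimConfig:
    """Cohort for screen-recovery runs: one 5.5-Mb planted block.

    The genome spans 100 Mb (1,000 screening windows of 100 kb) so the
    planted element stays a small fraction of the genome, as the Cook's
    distance outlier filter assumes; panel spacing of 1 kb matches the
    density of heterozygous SNPs in dog genomes.  The somatic-mutation rate
    is zeroed because the screen consumes only the germline panel.
    """
    return SimConfig(
        seed=seed,
        ht_blocks=[SCREEN_BLOCK],
        chrom_lengths={"chr7": 60_000_000, "chr1": 40_000_000},
        snp_spacing_bp=1000,
        somatic_rate_per_copy=0.0,
        rna_genes=0,
        rna_background_genes=0,
    )


def clock_validation_config(seed: int, **overrides) -> SimConfig:
    """Cohort for dating runs: default 11-block element, dense CpG panel.

    cpg_fraction 0.05 puts ~5.6e5 CpG sites inside the step segments;
    recovery precision against the nominal planted densities is limited by
    shared ancestral Poisson noise, which shrinks with the number of CpG
    sites.  The germline panel is thinned (the clock never reads it) and
    RNA is disabled.
    """
    params = dict(
        seed=seed,
        cpg_fraction=0.05,
        snp_spacing_bp=50_000,
        rna_genes=0,
        rna_background_genes=0,
    )
    params.update(overrides)
    return SimConfig(**params)


def hallmark_validation_config(seed: int, decoy_years: float | None = None) -> SimConfig:
    """Compact cohort for hallmark contrasts: one 3-Mb block.

    ``decoy_years`` switches the planted element to a parental-chromosome
    duplication of that age (the confounder the hallmarks must reject).
    """
    return SimConfig(
        seed=seed,
        ht_blocks=[("chr7", 3_000_000, 6_000_000, "+")],
        chrom_lengths={"chr7": 12_000_000, "chr1": 8_000_000},
        snp_spacing_bp=20_000,
        decoy_duplication_years=decoy_years,
        rna_genes=0,
        rna_background_genes=0,
    )


def expression_validation_config(seed: int) -> SimConfig:
    """Compact cohort for allelic-expression runs: RNA only matters.

    The panel is thinned and the somatic rate zeroed; gene counts mirror the
    study (73 informative-candidate genes on the element) over a background
    transcriptome.
    """
    return SimConfig(
        seed=seed,
        ht_blocks=[("chr7", 1_000_000, 4_000_000, "+")],
        chrom_lengths={"chr7": 10_000_000, "chr1": 6_000_000},
        snp_spacing_bp=50_000,
        somatic_rate_per_copy=0.0,
    )
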