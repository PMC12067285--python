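"""Synthetic transmissible-cancer cohorts with known ground truth.

The generator emulates the genetic structure that the flipping-SNP screen
relies on: a clonally propagated founder germline shared by every tumor, two
sister clades, somatic mutations accumulating along the transmission tree at
a constant per-copy rate (with a CpG C>T clock subset), integer copy-number
segments, and — in the carrier clade — an extra haplotype horizontally
transferred from a divergent donor genome, planted as a chain of oriented
blocks with matching copy-number steps and breakpoint junctions.  Read
counts are binomial draws from the tumor/host mixture under per-tumor purity
and sequencing depth.

Somatic CpG C>T mutations are simulated as explicit events with correct
phylogenetic sharing (trunk / clade / private / ht_haplotype) inside the
"tracked" regions (planted blocks plus flanking margins).  Non-CpG mutations
enter only as per-bin Poisson aggregates: downstream analyses consume them
solely as window densities, and event-level simulation at realistic
mammalian-tumor densities would produce millions of rows for no analytical
gain.

A duplication decoy mode (``decoy_duplication_years``) replaces the donor
haplotype with a duplicated parental homologue of the stated age.  The decoy
reproduces the copy-number step of a true transfer but not its somatic-VAF
pattern, which is what the hallmark tests are designed to distinguish.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .intervals import merge_intervals, sites_in_intervals

__all__ = [
    "SimConfig",
    "TruthSet",
    "Cohort",
    "simulate_cohort",
    "emit_read_counts",
    "default_blocks",
    "default_chrom_lengths",
]

# Published per-copy substitution rate (half the diploid rate) and the ages
# implied by the per-copy CpG C>T densities used as generator defaults.
RATE_PER_COPY = 3.435e-7
DEFAULT_LINEAGE_AGE = 2.21e-3 / RATE_PER_COPY  # parental density / rate
DEFAULT_HT_AGE = 2000.0

_TRANSITIONS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
_TRANSVERSIONS = [
    ("A", "C"), ("C", "A"), ("A", "T"), ("T", "A"),
    ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G"),
]

BIN_WIDTH = 1000  # 1-kb bins for the CpG clock


def default_chrom_lengths() -> dict[str, int]:
    """Desk-scale genome spanning the six implicated chromosomes."""
    return {
        "chr1": 10_000_000,
        "chr7": 9_000_000,
        "chr8": 7_000_000,
        "chr9": 6_000_000,
        "chr21": 5_000_000,
        "chr34": 4_000_000,
    }


def default_blocks() -> list[tuple[str, int, int, str]]:
    """Planted multi-block element: 11 oriented blocks on 6 chromosomes.

    Listed in chain order, running from the centromeric tip of chr21 to the
    centromeric tip of chr7 (canine chromosomes are acrocentric, so the
    centromere sits at the start of each chromosome).
    """
    return [
        ("chr21", 50_000, 1_250_000, "+"),
        ("chr1", 2_000_000, 3_500_000, "+"),
        ("chr8", 1_000_000, 2_200_000, "-"),
        ("chr9", 800_000, 1_700_000, "+"),
        ("chr1", 5_000_000, 5_800_000, "-"),
        ("chr34", 1_000_000, 1_800_000, "+"),
        ("chr8", 4_000_000, 4_600_000, "-"),
        ("chr34", 2_500_000, 3_000_000, "+"),
        ("chr9", 3_000_000, 3_500_000, "-"),
        ("chr1", 7_000_000, 7_500_000, "+"),
        ("chr7", 50_000, 2_850_000, "-"),
    ]


@dataclass
class SimConfig:
    """Generator parameters; defaults mirror the study cohort conditions.

    Rates are per site per year per chromosome copy; ages in years before
    present; purity in (0, 1].
    """

    n_tumors: int = 47
    clade_sizes: tuple[int, ...] = (7, 40)
    carrier_clade: int | None = 0
    founder_het_rate: float = 0.3
    donor_divergence: float = 0.3
    somatic_rate_per_copy: float = RATE_PER_COPY
    cpg_fraction: float = 0.01
    lineage_age_years: float = DEFAULT_LINEAGE_AGE
    clade_split_years: float = 2000.0
    clade_stem_years: float = 0.0
    ht_acquisition_years: float = DEFAULT_HT_AGE
    decoy_duplication_years: float | None = None
    ht_blocks: list[tuple[str, int, int, str]] = field(default_factory=default_blocks)
    chrom_lengths: dict[str, int] = field(default_factory=default_chrom_lengths)
    cn_profile: pd.DataFrame | None = None  # reserved; baseline is CN 2 everywhere
    snp_spacing_bp: int = 2000
    transversion_fraction: float = 1.0 / 3.0
    purity_range: tuple[float, float] = (0.7, 0.95)
    mean_depth: float = 77.0
    mutation_flank_frac: float = 0.6
    junction_support_mean: float = 25.0
    rna_genes: int = 73
    rna_background_genes: int = 1500
    rna_sites_per_gene: int = 3
    rna_mean_expression: float = 60.0
    rna_log_sd: float = 0.8
    rna_biological_log_sd: float = 0.3
    rna_size_factor_log_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_tumors <= 0:
            raise ConfigError("n_tumors must be positive")
        if sum(self.clade_sizes) != self.n_tumors:
            raise ConfigError("clade_sizes must sum to n_tumors")
        if any(s <= 0 for s in self.clade_sizes):
            raise ConfigError("clade sizes must be positive")
        if self.carrier_clade is not None and not (
            0 <= self.carrier_clade < len(self.clade_sizes)
        ):
            raise ConfigError("carrier_clade out of range")
        for name, prob in [
            ("founder_het_rate", self.founder_het_rate),
            ("donor_divergence", self.donor_divergence),
            ("cpg_fraction", self.cpg_fraction),
            ("transversion_fraction", self.transversion_fraction),
        ]:
            if not (0.0 <= prob <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.somatic_rate_per_copy < 0:
            raise ConfigError("somatic_rate_per_copy must be non-negative")
        if not (0.0 < self.purity_range[0] <= self.purity_range[1] <= 1.0):
            raise ConfigError("purity_range must satisfy 0 < lo <= hi <= 1")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")
        if not (
            0.0 <= self.ht_acquisition_years
            <= self.clade_split_years
            <= self.lineage_age_years
        ):
            raise ConfigError(
                "require ht_acquisition_years <= clade_split_years <= lineage_age_years"
            )
        if not (0.0 <= self.clade_stem_years <= self.clade_split_years):
            raise ConfigError("clade_stem_years must lie in [0, clade_split_years]")
        if self.decoy_duplication_years is not None and not (
            0.0 <= self.decoy_duplication_years <= self.lineage_age_years
        ):
            raise ConfigError("decoy_duplication_years must lie in [0, lineage_age_years]")
        seen: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, orient in self.ht_blocks:
            if chrom not in self.chrom_lengths:
                raise ConfigError(f"block chromosome {chrom} missing from chrom_lengths")
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ConfigError(f"block {chrom}:{start}-{end} outside chromosome")
            if orient not in ("+", "-"):
                raise ConfigError("block orientation must be '+' or '-'")
            for s, e in seen.get(chrom, []):
                if start < e and s < end:
                    raise ConfigError(f"blocks overlap on {chrom}")
            seen.setdefault(chrom, []).append((start, end))


@dataclass
class TruthSet:
    """Ground truth of one simulated cohort."""

    carrier_ids: list[str]
    planted_blocks: pd.DataFrame  # order, chrom, start, end, orientation
    per_mutation_origin: pd.DataFrame  # event_id, chrom, pos, origin
    donor_genotypes: pd.DataFrame  # chrom, pos, allele_index, allele (block sites)
    true_purity: dict[str, float]
    true_cn: pd.DataFrame
    ht_bin_counts: pd.DataFrame | None  # per-bin CpG C>T counts on the HT copy
    decoy: bool


@dataclass
class Cohort:
    """All observables of one simulated cohort plus its truth."""

    config: SimConfig
    samples: pd.DataFrame  # sample_id, kind, clade, purity, matched_host
    sites: pd.DataFrame  # chrom, pos, ref, alt, is_transversion
    ref_counts: pd.DataFrame  # sites x samples
    alt_counts: pd.DataFrame
    cn_segments: pd.DataFrame  # chrom, start, end, sample, total_cn
    junctions: pd.DataFrame  # BEDPE-style table
    bins: pd.DataFrame  # chrom, start, end, cpg_sites, in_block (tracked regions)
    counts_all: pd.DataFrame  # bins x tumors, all somatic mutations
    counts_cpg: pd.DataFrame  # bins x tumors, CpG C>T subset
    mut_events: pd.DataFrame  # per (event, tumor): reads, dosage, origin
    rna_counts: pd.DataFrame  # gene, chrom, pos, sample, allele, count
    rna_genotypes: pd.DataFrame  # gene, chrom, pos, tumor, source, allele, copies
    chrom_lengths: dict[str, int]
    truth: TruthSet

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.samples.loc[self.samples["kind"] == "tumor", "sample_id"])

    @property
    def host_ids(self) -> list[str]:
        return list(self.samples.loc[self.samples["kind"] == "host", "sample_id"])


def emit_read_counts(dosage, total_cn, purity, host_dosage, depth_mean, seed):
    """Sample (ref_reads, alt_reads) from the tumor/host mixture model.

    ``dosage`` is the number of cancer copies carrying the alternate allele
    (0 <= dosage <= total_cn) and ``host_dosage`` the host's alternate copies
    (of 2).  Depth is Poisson around ``depth_mean``; alternate reads are
    binomial with success probability
    ``(purity*dosage + (1-purity)*host_dosage) / (purity*total_cn + 2*(1-purity))``.
    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = np.asarray(dosage)
    c = np.asarray(total_cn)
    p = np.asarray(purity, dtype=float)
    h = np.asarray(host_dosage)
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ConfigError("purity must lie in (0, 1]")
    if np.any(k < 0) or np.any(k > c):
        raise ConfigError("dosage must satisfy 0 <= dosage <= total_cn")
    if np.any(h < 0) or np.any(h > 2):
        raise ConfigError("host_dosage must lie in [0, 2]")
    k, c, p, h = np.broadcast_arrays(k, c, p, h)
    q = (p * k + (1.0 - p) * h) / (p * c + 2.0 * (1.0 - p))
    depth = rng.poisson(depth_mean, size=q.shape)
    alt = rng.binomial(depth, q)
    return depth - alt, alt


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate one cohort; deterministic for a given config and seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    samples = _make_samples(config, rng)
    tumors = samples[samples["kind"] == "tumor"].reset_index(drop=True)
    hosts = samples[samples["kind"] == "host"].reset_index(drop=True)
    carriers = (
        list(tumors.loc[tumors["clade_index"] == config.carrier_clade, "sample_id"])
        if config.carrier_clade is not None
        else []
    )
    decoy = config.decoy_duplication_years is not None

    blocks = pd.DataFrame(
        config.ht_blocks, columns=["chrom", "start", "end", "orientation"]
    )
    blocks.insert(0, "order", np.arange(len(blocks)))

    sites, founder_dosage, donor_allele = _make_panel(config, rng, blocks)
    in_block = sites_in_intervals(
        sites["chrom"].to_numpy(), sites["pos"].to_numpy(), blocks
    )

    # host germline genotypes: independent diploid dogs from the same panel
    n_sites = len(sites)
    host_dosage = _draw_dosages(rng, (n_sites, len(hosts)), config.founder_het_rate)

    # per-tumor allele dosage K and total copy number C at panel sites
    carrier_cols = tumors["sample_id"].isin(carriers).to_numpy()
    K = np.repeat(founder_dosage[:, None], len(tumors), axis=1)
    C = np.full((n_sites, len(tumors)), 2, dtype=np.int64)
    if carriers:
        extra = np.zeros(n_sites, dtype=np.int64)
        if decoy:
            # duplicated homologue: carries the alt allele with prob dosage/2,
            # the carried homologue fixed per site across carriers
            extra[founder_dosage == 2] = 1
            het = founder_dosage == 1
            extra[het] = rng.integers(0, 2, size=int(het.sum()))
        else:
            extra = donor_allele.astype(np.int64)
        cell = np.outer(in_block, carrier_cols)
        K = K + np.where(cell, extra[:, None], 0)
        C = C + cell.astype(np.int64)

    # sequencing reads
    purity = tumors["purity"].to_numpy()
    host_of_tumor = tumors["matched_host"].map(
        {h: i for i, h in enumerate(hosts["sample_id"])}
    ).to_numpy()
    h_mat = host_dosage[:, host_of_tumor]
    t_ref, t_alt = emit_read_counts(K, C, purity[None, :], h_mat, config.mean_depth, rng)
    h_ref, h_alt = emit_read_counts(
        host_dosage, 2, 1.0, 0, config.mean_depth, rng
    )
    all_ids = list(tumors["sample_id"]) + list(hosts["sample_id"])
    ref_counts = pd.DataFrame(
        np.hstack([t_ref, h_ref]), index=sites.index, columns=all_ids
    )
    alt_counts = pd.DataFrame(
        np.hstack([t_alt, h_alt]), index=sites.index, columns=all_ids
    )

    cn_segments = _make_cn_segments(config, tumors, carriers, blocks)
    junctions = _make_junctions(config, rng, blocks)
    bins, counts_all, counts_cpg, mut_events, origins, ht_bin_counts = _make_mutations(
        config, rng, tumors, carriers, blocks, decoy
    )
    rna_counts, rna_genotypes = _make_rna(config, rng, tumors, hosts, carriers, blocks)

    donor_gt = pd.DataFrame(
        {
            "chrom": sites.loc[in_block, "chrom"].to_numpy(),
            "pos": sites.loc[in_block, "pos"].to_numpy(),
            "allele_index": donor_allele[in_block],
            "allele": np.where(
                donor_allele[in_block] == 1,
                sites.loc[in_block, "alt"].to_numpy(),
                sites.loc[in_block, "ref"].to_numpy(),
            ),
        }
    )

    truth = TruthSet(
        carrier_ids=carriers,
        planted_blocks=blocks,
        per_mutation_origin=origins,
        donor_genotypes=donor_gt,
        true_purity=dict(zip(tumors["sample_id"], purity)),
        true_cn=cn_segments.copy(),
        ht_bin_counts=ht_bin_counts,
        decoy=decoy,
    )
    return Cohort(
        config=replace(config),
        samples=samples,
        sites=sites,
        ref_counts=ref_counts,
        alt_counts=alt_counts,
        cn_segments=cn_segments,
        junctions=junctions,
        bins=bins,
        counts_all=counts_all,
        counts_cpg=counts_cpg,
        mut_events=mut_events,
        rna_counts=rna_counts,
        rna_genotypes=rna_genotypes,
        chrom_lengths=dict(config.chrom_lengths),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# internals


def _make_samples(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    idx = 0
    for clade_i, size in enumerate(config.clade_sizes):
        clade = f"clade{chr(ord('A') + clade_i)}"
        for _ in range(size):
            idx += 1
            tid = f"tumor_{idx:03d}"
            hid = f"host_{idx:03d}"
            rows.append((tid, "tumor", clade, clade_i, np.nan, hid))
            rows.append((hid, "host", "host", -1, 1.0, ""))
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "kind", "clade", "clade_index", "purity", "matched_host"],
    )
    is_tumor = df["kind"] == "tumor"
    lo, hi = config.purity_range
    df.loc[is_tumor, "purity"] = rng.uniform(lo, hi, size=int(is_tumor.sum()))
    df = pd.concat([df[is_tumor], df[~is_tumor]], ignore_index=True)
    return df


def _draw_dosages(rng: np.random.Generator, shape, het_rate: float) -> np.ndarray:
    """Diploid alt dosage: het with prob het_rate, otherwise hom ref/alt equally."""
    u = rng.random(shape)
    dosage = np.where(u < het_rate, 1, np.where(rng.random(shape) < 0.5, 0, 2))
    return dosage.astype(np.int64)


def _make_panel(config, rng, blocks):
    chroms, positions = [], []
    for chrom, length in config.chrom_lengths.items():
        n = max(int(length // config.snp_spacing_bp), 1)
        pos = np.unique(rng.integers(1, length + 1, size=n))
        chroms.append(np.repeat(chrom, len(pos)))
        positions.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    n_sites = len(pos)

    is_tv = rng.random(n_sites) < config.transversion_fraction
    pair_ts = rng.integers(0, len(_TRANSITIONS), size=n_sites)
    pair_tv = rng.integers(0, len(_TRANSVERSIONS), size=n_sites)
    ts = np.array(_TRANSITIONS)
    tv = np.array(_TRANSVERSIONS)
    ref = np.where(is_tv, tv[pair_tv, 0], ts[pair_ts, 0])
    alt = np.where(is_tv, tv[pair_tv, 1], ts[pair_ts, 1])

    sites = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "is_transversion": is_tv}
    )

    founder_dosage = _draw_dosages(rng, n_sites, config.founder_het_rate)
    # donor haploid allele: a random founder allele, redrawn uniformly from the
    # panel's two alleles with probability donor_divergence
    base = (rng.random(n_sites) < founder_dosage / 2.0).astype(np.int64)
    redraw = rng.random(n_sites) < config.donor_divergence
    uniform = rng.integers(0, 2, size=n_sites)
    donor_allele = np.where(redraw, uniform, base)
    return sites, founder_dosage, donor_allele


def _make_cn_segments(config, tumors, carriers, blocks):
    rows = []
    block_lookup: dict[str, list[tuple[int, int]]] = {}
    for _, b in blocks.iterrows():
        block_lookup.setdefault(b["chrom"], []).append((int(b["start"]), int(b["end"])))
    for chrom, length in config.chrom_lengths.items():
        cuts = sorted({0, length, *[x for se in block_lookup.get(chrom, []) for x in se]})
        for s, e in zip(cuts[:-1], cuts[1:]):
            is_block = any(bs <= s and e <= be for bs, be in block_lookup.get(chrom, []))
            for tid in tumors["sample_id"]:
                cn = 2 + (1 if (is_block and tid in carriers) else 0)
                rows.append((chrom, s, e, tid, cn))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "total_cn"])


def _block_end(block, which: str) -> tuple[str, int, str]:
    """1-based breakend of a block: ('left' = start, 'right' = end)."""
    if which == "left":
        return block["chrom"], int(block["start"]) + 1, "left"
    return block["chrom"], int(block["end"]), "right"


def _make_junctions(config, rng, blocks):
    """BEDPE junction rows joining consecutive blocks of the planted chain."""
    rows = []
    for i in range(len(blocks) - 1):
        a, b = blocks.iloc[i], blocks.iloc[i + 1]
        exit_end = _block_end(a, "right" if a["orientation"] == "+" else "left")
        entry_end = _block_end(b, "left" if b["orientation"] == "+" else "right")
        support = max(3, int(rng.poisson(config.junction_support_mean)))
        rows.append(
            (
                exit_end[0], exit_end[1] - 1, exit_end[1],
                entry_end[0], entry_end[1] - 1, entry_end[1],
                f"junction_{i:02d}", support,
                "+" if exit_end[2] == "right" else "-",
                "+" if entry_end[2] == "right" else "-",
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom1", "start1", "end1", "chrom2", "start2", "end2",
            "name", "support", "strand1", "strand2",
        ],
    )


def _make_bins(config, blocks):
    tracked = []
    for _, b in blocks.iterrows():
        margin = int(config.mutation_flank_frac * (b["end"] - b["start"]))
        tracked.append(
            (
                b["chrom"],
                max(0, (b["start"] - margin) // BIN_WIDTH * BIN_WIDTH),
                min(
                    config.chrom_lengths[b["chrom"]] // BIN_WIDTH * BIN_WIDTH,
                    -((-(b["end"] + margin)) // BIN_WIDTH) * BIN_WIDTH,
                ),
            )
        )
    tracked = merge_intervals(pd.DataFrame(tracked, columns=["chrom", "start", "end"]))
    rows = []
    for _, t in tracked.iterrows():
        starts = np.arange(t["start"], t["end"], BIN_WIDTH)
        for s in starts:
            rows.append((t["chrom"], int(s), int(s) + BIN_WIDTH))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    mid = (bins["start"] + bins["end"]) // 2
    bins["in_block"] = sites_in_intervals(bins["chrom"].to_numpy(), mid.to_numpy(), blocks)
    return bins


def _make_mutations(config, rng, tumors, carriers, blocks, decoy):
    """CpG C>T events plus per-bin aggregate mutation counts."""
    bins = _make_bins(config, blocks)
    n_bins = len(bins)
    bins["cpg_sites"] = rng.binomial(BIN_WIDTH, config.cpg_fraction, size=n_bins)
    cpg = bins["cpg_sites"].to_numpy().astype(float)
    noncpg = BIN_WIDTH - cpg
    in_block = bins["in_block"].to_numpy()
    tumor_ids = list(tumors["sample_id"])
    n_t = len(tumor_ids)
    carrier_idx = [tumor_ids.index(t) for t in carriers]
    rate = config.somatic_rate_per_copy
    split = config.clade_split_years
    stem = config.clade_stem_years
    dup_age = config.decoy_duplication_years if decoy else None
    extra_years = (
        dup_age if decoy else (config.ht_acquisition_years if carriers else 0.0)
    )

    # --- event classes: (origin, branch years, bin scope, member tumor idx,
    #                     copies at risk, age window)
    classes = []
    trunk_years = config.lineage_age_years - split
    classes.append(("trunk", trunk_years, slice(None), list(range(n_t)), 2, (split, config.lineage_age_years)))
    for clade_i in sorted(tumors["clade_index"].unique()):
        members = list(np.flatnonzero((tumors["clade_index"] == clade_i).to_numpy()))
        if stem > 0:
            classes.append(("clade", stem, slice(None), members, 2, (split - stem, split)))
    for ti in range(n_t):
        classes.append(("private", split - stem, slice(None), [ti], 2, (0.0, split - stem)))
    if carriers and not decoy:
        for ti in carrier_idx:
            classes.append(
                ("ht_haplotype", config.ht_acquisition_years, in_block, [ti], 1,
                 (0.0, config.ht_acquisition_years))
            )
    if carriers and decoy:
        shared = max(0.0, dup_age - split)
        if shared > 0:
            classes.append(("clade", shared, in_block, carrier_idx, 1, (split, dup_age)))
        priv = min(dup_age, split)
        for ti in carrier_idx:
            classes.append(("private", priv, in_block, [ti], 1, (0.0, priv)))

    ev_rows = []  # unique events
    eid = 0
    for origin, years, scope, members, copies, age_win in classes:
        w = cpg[scope] if not isinstance(scope, slice) else cpg
        total = float(w.sum())
        if total <= 0 or years <= 0:
            continue
        n_ev = rng.poisson(rate * years * total * copies)
        if n_ev == 0:
            continue
        scope_idx = np.flatnonzero(scope) if not isinstance(scope, slice) else np.arange(n_bins)
        bi = scope_idx[rng.choice(len(scope_idx), size=n_ev, p=w / total)]
        pos = bins["start"].to_numpy()[bi] + rng.integers(1, BIN_WIDTH + 1, size=n_ev)
        homolog = rng.integers(0, 2, size=n_ev)
        age = rng.uniform(age_win[0], age_win[1], size=n_ev)
        on_extra = origin in ("ht_haplotype",) or (decoy and copies == 1)
        for j in range(n_ev):
            ev_rows.append(
                (eid, bins["chrom"].iat[bi[j]], int(pos[j]), int(bi[j]), origin,
                 int(homolog[j]), float(age[j]), tuple(members), bool(on_extra))
            )
            eid += 1

    origins = pd.DataFrame(
        [(e[0], e[1], e[2], e[4]) for e in ev_rows],
        columns=["event_id", "chrom", "pos", "origin"],
    )

    # --- expand events to per-tumor rows with read counts
    counts_cpg = np.zeros((n_bins, n_t), dtype=np.int64)
    ht_counts = np.zeros((n_bins, len(carrier_idx)), dtype=np.int64)
    rec = {k: [] for k in ("event_id", "chrom", "pos", "bin", "origin", "sample_idx", "k", "c", "extra")}
    for eid_, chrom, pos, bi, origin, homolog, age, members, on_extra in ev_rows:
        for ti in members:
            is_carrier = ti in carrier_idx
            blocked = bool(in_block[bi])
            c = 3 if (is_carrier and blocked and carriers) else 2
            k = 1
            if decoy and is_carrier and blocked and not on_extra:
                # events predating the duplication ride both copies of the
                # duplicated homologue
                if homolog == 0 and age > dup_age:
                    k = 2
            rec["event_id"].append(eid_)
            rec["chrom"].append(chrom)
            rec["pos"].append(pos)
            rec["bin"].append(bi)
            rec["origin"].append(origin)
            rec["sample_idx"].append(ti)
            rec["k"].append(k)
            rec["c"].append(c)
            rec["extra"].append(on_extra)
            counts_cpg[bi, ti] += 1
            if on_extra and not decoy:
                ht_counts[bi, carrier_idx.index(ti)] += 1

    mut_events = pd.DataFrame(rec)
    if len(mut_events):
        purity = tumors["purity"].to_numpy()[mut_events["sample_idx"].to_numpy()]
        k = mut_events["k"].to_numpy()
        c = mut_events["c"].to_numpy()
        q = purity * k / (purity * c + 2.0 * (1.0 - purity))
        depth = rng.poisson(config.mean_depth, size=len(mut_events))
        alt = rng.binomial(depth, q)
        mut_events["ref_reads"] = depth - alt
        mut_events["alt_reads"] = alt
        mut_events["sample"] = [tumor_ids[i] for i in mut_events["sample_idx"]]
        mut_events["total_cn"] = c
        mut_events["alt_copies"] = k
        mut_events = mut_events.drop(columns=["sample_idx", "k", "c"])
    else:
        mut_events = pd.DataFrame(
            columns=[
                "event_id", "chrom", "pos", "bin", "origin", "extra",
                "ref_reads", "alt_reads", "sample", "total_cn", "alt_copies",
            ]
        )

    # --- non-CpG aggregate layer (window densities only)
    lam_parental = rate * config.lineage_age_years * noncpg * 2.0
    noncpg_counts = rng.poisson(lam_parental[:, None], size=(n_bins, n_t))
    if carriers and extra_years > 0:
        lam_extra = rate * extra_years * noncpg * in_block
        extra_counts = rng.poisson(lam_extra[:, None], size=(n_bins, len(carrier_idx)))
        for j, ti in enumerate(carrier_idx):
            noncpg_counts[:, ti] += extra_counts[:, j]

    counts_all = pd.DataFrame(counts_cpg + noncpg_counts, columns=tumor_ids)
    counts_cpg_df = pd.DataFrame(counts_cpg, columns=tumor_ids)
    ht_bin_counts = (
        pd.DataFrame(ht_counts, columns=carriers) if (carriers and not decoy) else None
    )
    return bins, counts_all, counts_cpg_df, mut_events, origins, ht_bin_counts


def _make_rna(config, rng, tumors, hosts, carriers, blocks):
    """Per-allele RNA read counts for genes on and off the planted element.

    Expression is per-copy: cancer parental copies and the HT copy follow one
    lognormal program, infiltrating host cells an independent one.  Counts
    are Poisson around size-factor-scaled expectations with per-(gene, tumor)
    lognormal biological variability, giving the overdispersion of real bulk
    RNA-seq.  Background genes outside the element (diploid in every tumor,
    no HT copy) anchor the median-of-ratios normalisation the way a full
    transcriptome does in real data — without them the element's extra copy
    would bias carrier size factors.
    """
    n_genes = config.rna_genes
    empty_counts = pd.DataFrame(columns=["gene", "chrom", "pos", "sample", "allele", "count"])
    empty_gt = pd.DataFrame(columns=["gene", "chrom", "pos", "tumor", "source", "allele", "copies"])
    if n_genes == 0:
        return empty_counts, empty_gt

    tumor_ids = np.array(tumors["sample_id"], dtype=object)
    n_t = len(tumor_ids)
    purity = tumors["purity"].to_numpy()
    is_carrier = np.isin(tumor_ids, np.array(carriers, dtype=object))
    mu = np.log(config.rna_mean_expression) - config.rna_log_sd**2 / 2.0
    bio_mu = -config.rna_biological_log_sd**2 / 2.0
    size_factors = rng.lognormal(0.0, config.rna_size_factor_log_sd, size=n_t)

    def gene_tables(prefix, n_g, n_s, gchrom, gpos, founder, host_dosage, ht_allele):
        """Counts and genotype rows for one batch of genes.

        Shapes: founder/host_dosage (n_g, n_s[, n_t]); ht_allele (n_g, n_s)
        or None for genes off the element.
        """
        lam_c = rng.lognormal(mu, config.rna_log_sd, size=n_g)
        lam_h = rng.lognormal(mu, config.rna_log_sd, size=n_g)
        noise_c = rng.lognormal(bio_mu, config.rna_biological_log_sd, size=(n_g, n_s, n_t))
        noise_h = rng.lognormal(bio_mu, config.rna_biological_log_sd, size=(n_g, n_s, n_t))

        # copies per (gene, site, tumor, allele); allele axis: 0 = A/ref, 1 = G/alt
        f = founder[:, :, None]
        cancer = np.stack([2 - f, f], axis=-1) * np.ones((1, 1, n_t, 1), dtype=np.int64)
        host = np.stack([2 - host_dosage, host_dosage], axis=-1)
        if ht_allele is not None:
            d = ht_allele[:, :, None]
            ht = np.stack([(d == 0), (d == 1)], axis=-1).astype(np.int64) * is_carrier[None, :, None].reshape(1, 1, n_t, 1)
        else:
            ht = np.zeros_like(cancer)

        p = purity[None, None, :, None]
        rate_c = (lam_c[:, None, None] * noise_c)[:, :, :, None]
        rate_h = (lam_h[:, None, None] * noise_h)[:, :, :, None]
        expected = size_factors[None, None, :, None] * (
            p * rate_c * (cancer + ht) + (1.0 - p) * rate_h * host
        )
        counts = rng.poisson(expected)

        genes = np.array([f"{prefix}{g:03d}" for g in range(n_g)], dtype=object)
        shape = (n_g, n_s, n_t, 2)
        gene_col = np.broadcast_to(genes[:, None, None, None], shape)
        chrom_col = np.broadcast_to(np.asarray(gchrom, dtype=object)[:, None, None, None], shape)
        pos_site = gpos[:, None] + 50 * np.arange(n_s)[None, :]  # exonic variants
        pos_col = np.broadcast_to(pos_site[:, :, None, None], shape)
        sample_col = np.broadcast_to(tumor_ids[None, None, :, None], shape)
        allele_col = np.broadcast_to(np.array(["A", "G"], dtype=object)[None, None, None, :], shape)
        counts_df = pd.DataFrame(
            {
                "gene": gene_col.ravel(),
                "chrom": chrom_col.ravel(),
                "pos": pos_col.ravel(),
                "sample": sample_col.ravel(),
                "allele": allele_col.ravel(),
                "count": counts.ravel(),
            }
        )
        gt_parts = []
        for source, copies in (("cancer", cancer), ("host", host), ("HT", ht)):
            mask = copies.ravel() > 0
            if not mask.any():
                continue
            gt_parts.append(
                pd.DataFrame(
                    {
                        "gene": gene_col.ravel()[mask],
                        "chrom": chrom_col.ravel()[mask],
                        "pos": pos_col.ravel()[mask],
                        "tumor": sample_col.ravel()[mask],
                        "source": source,
                        "allele": allele_col.ravel()[mask],
                        "copies": copies.ravel()[mask],
                    }
                )
            )
        return counts_df, pd.concat(gt_parts, ignore_index=True)

    # element genes: inside blocks, HT copy present in carriers
    n_sites = config.rna_sites_per_gene
    lens = (blocks["end"] - blocks["start"]).to_numpy().astype(float)
    pick = rng.choice(len(blocks), size=n_genes, p=lens / lens.sum())
    offs = rng.integers(0, (blocks["end"] - blocks["start"]).to_numpy()[pick])
    gchrom = blocks["chrom"].to_numpy()[pick]
    gpos = blocks["start"].to_numpy()[pick] + offs + 1
    founder = _draw_dosages(rng, (n_genes, n_sites), config.founder_het_rate)
    base = (rng.random((n_genes, n_sites)) < founder / 2.0).astype(np.int64)
    redraw = rng.random((n_genes, n_sites)) < config.donor_divergence
    donor = np.where(redraw, rng.integers(0, 2, size=(n_genes, n_sites)), base)
    host_dosage = _draw_dosages(rng, (n_genes, n_sites, n_t), config.founder_het_rate)
    counts_el, gt_el = gene_tables(
        "gene_", n_genes, n_sites, gchrom, gpos, founder, host_dosage,
        donor if carriers else None,
    )

    # background genes: outside the element, diploid, never HT-informative
    n_bg = config.rna_background_genes
    if n_bg:
        chrom_names = list(config.chrom_lengths)
        lengths = np.array([config.chrom_lengths[c] for c in chrom_names], dtype=float)
        block_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for _, b in blocks.iterrows():
            block_by_chrom.setdefault(b["chrom"], []).append((int(b["start"]), int(b["end"])))
        bg_chrom, bg_pos = [], []
        for _ in range(n_bg):
            while True:
                ci = int(rng.choice(len(chrom_names), p=lengths / lengths.sum()))
                pos = int(rng.integers(1, int(lengths[ci]) + 1))
                if not any(s < pos <= e for s, e in block_by_chrom.get(chrom_names[ci], [])):
                    break
            bg_chrom.append(chrom_names[ci])
            bg_pos.append(pos)
        bg_founder = _draw_dosages(rng, (n_bg, 1), config.founder_het_rate)
        bg_host = _draw_dosages(rng, (n_bg, 1, n_t), config.founder_het_rate)
        counts_bg, gt_bg = gene_tables(
            "bg_gene_", n_bg, 1, np.array(bg_chrom, dtype=object), np.array(bg_pos),
            bg_founder, bg_host, None,
        )
        counts_el = pd.concat([counts_el, counts_bg], ignore_index=True)
        gt_el = pd.concat([gt_el, gt_bg], ignore_index=True)

    return counts_el, gt_el
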