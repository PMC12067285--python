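"""File-based orchestration of the analysis stages.

Each stage reads conventional file names from a working directory and
writes its outputs there, so stages can be re-run individually and partial
pipelines resume from existing intermediates.  Missing upstream files raise
:class:`DependencyError` naming the stage that should have produced them.
The stage registry at the bottom drives both the CLI and the run manifest.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, allelexpr, chainasm, cpgclock, flipscan, genostate, hallmarks, hapinfer, io
from .errors import ConfigError, DependencyError
from .intervals import cn_matrix, merge_intervals
from .simcohort import SimConfig, simulate_cohort

NO_TRANSFER_MESSAGE = "no horizontal transfer detected"


def genotype_cohort(cohort, min_depth: int = genostate.DEFAULT_MIN_DEPTH):
    """In-memory genotype calling for a simulated cohort.

    Returns ``(tumor_ids, alt_copies, states, consensus)``.
    """
    tumors = cohort.samples[cohort.samples["kind"] == "tumor"]
    tumor_ids = list(tumors["sample_id"])
    host_frac = np.column_stack(
        [
            genostate.host_dosage_fractions(
                cohort.ref_counts[h].to_numpy(), cohort.alt_counts[h].to_numpy(), min_depth
            )
            for h in tumors["matched_host"]
        ]
    )
    cn = cn_matrix(cohort.cn_segments, cohort.sites, tumor_ids).to_numpy()
    k, states, _ = genostate.classify_genotypes(
        cohort.ref_counts[tumor_ids].to_numpy(),
        cohort.alt_counts[tumor_ids].to_numpy(),
        tumors["purity"].to_numpy()[None, :],
        cn,
        host_frac,
        min_depth,
    )
    consensus = genostate.consensus_states(states)
    return tumor_ids, k, states, consensus


def screen_cohort(cohort, **region_params):
    """In-memory flipping-SNP screen for a simulated cohort.

    Returns ``(tumor_ids, flips, regions, window_stats)``.
    """
    tumor_ids, _, states, consensus = genotype_cohort(cohort)
    screened = flipscan.screened_segments(cohort.cn_segments, cohort.sites, consensus)
    flips = flipscan.call_flipping_snps(states, consensus, cohort.sites, tumor_ids, screened)
    regions, stats = flipscan.detect_candidate_regions(flips, screened, tumor_ids, **region_params)
    return tumor_ids, flips, regions, stats

FILES = {
    "samples": "samples.tsv",
    "sites": "sites.tsv",
    "ad_ref": "ad_ref.tsv",
    "ad_alt": "ad_alt.tsv",
    "cn": "cn_segments.bed",
    "junctions": "junctions.bedpe",
    "bins": "bins.tsv",
    "counts_all": "counts_all.tsv",
    "counts_cpg": "counts_cpg.tsv",
    "mut_events": "mut_events.tsv",
    "rna_counts": "rna_counts.tsv",
    "rna_genotypes": "rna_genotypes.tsv",
    "truth": "truth.json",
    "states": "genotype_states.tsv",
    "alt_copies": "genotype_alt_copies.tsv",
    "consensus": "consensus.tsv",
    "screened": "screened_segments.tsv",
    "flips": "flips.tsv",
    "window_stats": "window_stats.tsv",
    "regions": "candidate_regions.tsv",
    "carriers": "carriers.json",
    "hallmarks": "hallmarks.json",
    "chain": "chain.tsv",
    "chain_summary": "chain_summary.json",
    "clock": "clock.json",
    "ht_genotypes": "ht_genotypes.tsv",
    "expression": "expression.tsv",
    "expression_compare": "expression_compare.json",
}


def _path(outdir, key) -> Path:
    return Path(outdir) / FILES[key]


def _require(outdir, keys, stage: str, produced_by: str) -> None:
    missing = [FILES[k] for k in keys if not _path(outdir, k).exists()]
    if missing:
        raise DependencyError(
            f"stage '{stage}' is missing inputs {missing}; run stage '{produced_by}' first"
        )


def build_sim_config(params: dict) -> SimConfig:
    params = dict(params or {})
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(params) - known
    if unknown:
        raise ConfigError(f"unknown simulate options: {sorted(unknown)}")
    for key in ("clade_sizes", "purity_range"):
        if key in params:
            params[key] = tuple(params[key])
    if "ht_blocks" in params and params["ht_blocks"] is not None:
        params["ht_blocks"] = [tuple(b) for b in params["ht_blocks"]]
    return SimConfig(**params)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(outdir, params: dict, seed: int | None = None, write_vcf: bool | None = None):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = dict(params or {})
    if write_vcf is None:
        write_vcf = bool(params.pop("write_vcf", False))
    else:
        params.pop("write_vcf", None)
    if seed is not None:
        params["seed"] = seed
    config = build_sim_config(params)
    cohort = simulate_cohort(config)
    io.write_tsv(cohort.samples, _path(outdir, "samples"))
    io.write_tsv(cohort.sites, _path(outdir, "sites"))
    io.write_matrix(cohort.ref_counts, _path(outdir, "ad_ref"))
    io.write_matrix(cohort.alt_counts, _path(outdir, "ad_alt"))
    io.write_bed_segments(cohort.cn_segments, _path(outdir, "cn"))
    io.write_bedpe(cohort.junctions, _path(outdir, "junctions"))
    io.write_tsv(cohort.bins, _path(outdir, "bins"))
    io.write_matrix(cohort.counts_all, _path(outdir, "counts_all"))
    io.write_matrix(cohort.counts_cpg, _path(outdir, "counts_cpg"))
    io.write_tsv(cohort.mut_events, _path(outdir, "mut_events"))
    io.write_tsv(cohort.rna_counts, _path(outdir, "rna_counts"))
    io.write_tsv(cohort.rna_genotypes, _path(outdir, "rna_genotypes"))
    truth = cohort.truth
    io.write_json(
        {
            "carrier_ids": truth.carrier_ids,
            "planted_blocks": truth.planted_blocks.to_dict("records"),
            "true_purity": truth.true_purity,
            "decoy": truth.decoy,
            "chrom_lengths": cohort.chrom_lengths,
        },
        _path(outdir, "truth"),
    )
    if write_vcf:
        io.write_vcf(
            cohort.sites, cohort.ref_counts, cohort.alt_counts,
            cohort.chrom_lengths, outdir / "site_counts.vcf",
        )
    return cohort


def _load_core(outdir):
    samples = io.read_tsv(_path(outdir, "samples"))
    sites = io.read_tsv(_path(outdir, "sites"))
    ref = io.read_matrix(_path(outdir, "ad_ref"))
    alt = io.read_matrix(_path(outdir, "ad_alt"))
    cn = io.read_bed_segments(_path(outdir, "cn"))
    return samples, sites, ref, alt, cn


def stage_genotype(outdir, params: dict):
    _require(outdir, ["samples", "sites", "ad_ref", "ad_alt", "cn"], "genotype", "simulate")
    params = dict(params or {})
    min_depth = int(params.get("min_depth", genostate.DEFAULT_MIN_DEPTH))
    min_call_fraction = float(params.get("min_call_fraction", genostate.DEFAULT_MIN_CALL_FRACTION))
    min_het_fraction = float(params.get("min_het_fraction", flipscan.DEFAULT_MIN_HET_FRACTION))

    samples, sites, ref, alt, cn = _load_core(outdir)
    tumors = samples[samples["kind"] == "tumor"]
    tumor_ids = list(tumors["sample_id"])
    host_frac = np.column_stack(
        [
            genostate.host_dosage_fractions(
                ref[h].to_numpy(), alt[h].to_numpy(), min_depth
            )
            if h in ref.columns
            else np.zeros(len(sites))
            for h in tumors["matched_host"]
        ]
    )
    cn_mat = cn_matrix(cn, sites, tumor_ids).to_numpy()
    purity = tumors["purity"].to_numpy()
    k, states, conf = genostate.classify_genotypes(
        ref[tumor_ids].to_numpy(), alt[tumor_ids].to_numpy(),
        purity[None, :], cn_mat, host_frac, min_depth,
    )
    consensus = genostate.consensus_states(states, min_call_fraction)
    screened = flipscan.screened_segments(cn, sites, consensus, 2, min_het_fraction)

    io.write_matrix(pd.DataFrame(states, columns=tumor_ids), _path(outdir, "states"))
    io.write_matrix(pd.DataFrame(k, columns=tumor_ids), _path(outdir, "alt_copies"))
    cons = sites.copy()
    cons["consensus"] = consensus
    io.write_tsv(cons, _path(outdir, "consensus"))
    io.write_tsv(screened, _path(outdir, "screened"))
    return states, consensus, screened


def stage_screen(outdir, params: dict):
    _require(outdir, ["states", "consensus", "screened"], "screen", "genotype")
    params = dict(params or {})
    samples = io.read_tsv(_path(outdir, "samples"))
    sites = io.read_tsv(_path(outdir, "sites"))
    states = io.read_matrix(_path(outdir, "states"))
    consensus = io.read_tsv(_path(outdir, "consensus"))["consensus"].to_numpy()
    screened = io.read_tsv(_path(outdir, "screened"))
    tumor_ids = list(samples.loc[samples["kind"] == "tumor", "sample_id"])

    flips = flipscan.call_flipping_snps(
        states[tumor_ids].to_numpy(), consensus, sites, tumor_ids, screened
    )
    regions, stats = flipscan.detect_candidate_regions(
        flips, screened, tumor_ids,
        window=int(params.get("window", flipscan.DEFAULT_WINDOW)),
        z_min=float(params.get("z_min", flipscan.DEFAULT_Z_MIN)),
        min_run=int(params.get("min_run", flipscan.DEFAULT_MIN_RUN)),
        merge_gap=int(params.get("merge_gap", flipscan.DEFAULT_MERGE_GAP)),
    )
    carriers = sorted(regions["sample_id"].unique())
    io.write_tsv(flips, _path(outdir, "flips"))
    io.write_tsv(stats, _path(outdir, "window_stats"))
    io.write_tsv(regions, _path(outdir, "regions"))
    io.write_json({"carrier_ids": carriers, "n_regions": int(len(regions))}, _path(outdir, "carriers"))
    return regions, carriers


def _carriers_or_none(outdir):
    carriers = io.read_json(_path(outdir, "carriers"))["carrier_ids"]
    return carriers if carriers else None


def stage_hallmarks(outdir, params: dict):
    _require(outdir, ["regions", "carriers", "cn", "mut_events", "bins", "counts_all"], "hallmarks", "screen")
    params = dict(params or {})
    carriers = _carriers_or_none(outdir)
    if carriers is None:
        io.write_json({"note": NO_TRANSFER_MESSAGE, "reports": []}, _path(outdir, "hallmarks"))
        return []
    samples = io.read_tsv(_path(outdir, "samples"))
    regions = io.read_tsv(_path(outdir, "regions"))
    cn = io.read_bed_segments(_path(outdir, "cn"))
    muts = io.read_tsv(_path(outdir, "mut_events"))
    bins = io.read_tsv(_path(outdir, "bins"))
    counts_all = io.read_matrix(_path(outdir, "counts_all"))
    truth = io.read_json(_path(outdir, "truth")) if _path(outdir, "truth").exists() else {}
    chrom_lengths = truth.get("chrom_lengths", {})
    tumor_ids = list(samples.loc[samples["kind"] == "tumor", "sample_id"])
    noncarriers = [t for t in tumor_ids if t not in carriers]
    purity = dict(zip(samples["sample_id"], samples["purity"]))

    merged = merge_intervals(regions[["chrom", "start", "end"]])
    reports = []
    for _, reg in merged.iterrows():
        region = (reg["chrom"], int(reg["start"]), int(reg["end"]))
        exclude = merged[
            (merged["chrom"] == region[0])
            & ~((merged["start"] == region[1]) & (merged["end"] == region[2]))
        ]
        for carrier in carriers:
            rep = hallmarks.evaluate_region(
                region, cn, carriers, noncarriers, muts, purity, bins, counts_all,
                carrier_for_density=carrier,
                chrom_length=chrom_lengths.get(region[0]),
                exclude=exclude,
                window=int(params.get("window", hallmarks.DEFAULT_DENSITY_WINDOW)),
            )
            d = asdict(rep)
            d["carrier"] = carrier
            reports.append(d)
    io.write_json({"reports": reports}, _path(outdir, "hallmarks"))
    return reports


def stage_chain(outdir, params: dict):
    _require(outdir, ["carriers", "cn", "junctions"], "chain", "screen")
    params = dict(params or {})
    carriers = _carriers_or_none(outdir)
    if carriers is None:
        io.write_json({"note": NO_TRANSFER_MESSAGE}, _path(outdir, "chain_summary"))
        io.write_tsv(pd.DataFrame(columns=["chrom", "start", "end", "order", "orientation"]), _path(outdir, "chain"))
        return None
    samples = io.read_tsv(_path(outdir, "samples"))
    cn = io.read_bed_segments(_path(outdir, "cn"))
    junctions = io.read_bedpe(_path(outdir, "junctions"))
    truth = io.read_json(_path(outdir, "truth")) if _path(outdir, "truth").exists() else {}
    tumor_ids = list(samples.loc[samples["kind"] == "tumor", "sample_id"])
    noncarriers = [t for t in tumor_ids if t not in carriers]
    segments = cpgclock.select_informative_segments(cn, carriers, noncarriers)
    chain = chainasm.assemble_chain(
        junctions, segments,
        tolerance=int(params.get("tolerance", chainasm.DEFAULT_TOLERANCE)),
        min_support=int(params.get("min_support", chainasm.DEFAULT_MIN_SUPPORT)),
        chrom_lengths=truth.get("chrom_lengths") or None,
    )
    summary = chainasm.summarize_element(chain)
    io.write_tsv(chainasm.chain_to_frame(chain), _path(outdir, "chain"))
    io.write_json(
        {
            "n_blocks": summary.n_blocks,
            "n_chromosomes": summary.n_chromosomes,
            "total_length": summary.total_length,
            "termini": list(summary.termini),
            "circular": chain.circular,
        },
        _path(outdir, "chain_summary"),
    )
    return chain


def stage_date(outdir, params: dict):
    _require(outdir, ["carriers", "cn", "bins", "counts_cpg"], "date", "screen")
    params = dict(params or {})
    carriers = _carriers_or_none(outdir)
    if carriers is None:
        io.write_json({"note": NO_TRANSFER_MESSAGE}, _path(outdir, "clock"))
        return None
    samples = io.read_tsv(_path(outdir, "samples"))
    cn = io.read_bed_segments(_path(outdir, "cn"))
    bins = io.read_tsv(_path(outdir, "bins"))
    counts_cpg = io.read_matrix(_path(outdir, "counts_cpg"))
    tumor_ids = list(samples.loc[samples["kind"] == "tumor", "sample_id"])
    noncarriers = [t for t in tumor_ids if t not in carriers]
    est = cpgclock.estimate_clock(
        counts_cpg, bins, cn, carriers, noncarriers,
        rate_diploid=float(params.get("rate_diploid", cpgclock.DEFAULT_RATE_DIPLOID)),
    )
    io.write_json(
        {
            "parental_density": asdict(est.parental),
            "ht_density": asdict(est.ht),
            "ht_range": list(est.ht_range),
            "rate_per_copy": est.rate_per_copy,
            "age_years": est.age_years,
            "age_raw": est.age_raw,
            "age_ci": list(est.age_ci),
        },
        _path(outdir, "clock"),
    )
    return est


def stage_haplotype(outdir, params: dict):
    _require(outdir, ["carriers", "samples", "sites", "ad_ref", "ad_alt", "cn"], "haplotype", "screen")
    params = dict(params or {})
    carriers = _carriers_or_none(outdir)
    if carriers is None:
        io.write_tsv(
            pd.DataFrame(columns=["chrom", "pos", "ht_allele", "llr", "parental_dosage", "reason"]),
            _path(outdir, "ht_genotypes"),
        )
        return []
    samples, sites, ref, alt, cn = _load_core(outdir)
    tumor_ids = list(samples.loc[samples["kind"] == "tumor", "sample_id"])
    noncarriers = [t for t in tumor_ids if t not in carriers]
    segments = cpgclock.select_informative_segments(cn, carriers, noncarriers)
    calls = hapinfer.infer_ht_genotypes(
        sites, ref, alt, samples, cn, segments, carriers, noncarriers,
        transversions_only=bool(params.get("transversions_only", True)),
        llr_threshold=float(params.get("llr_threshold", hapinfer.DEFAULT_LLR_THRESHOLD)),
    )
    io.write_tsv(hapinfer.genotypes_to_frame(calls), _path(outdir, "ht_genotypes"))
    return calls


def stage_expression(outdir, params: dict):
    _require(outdir, ["rna_counts", "rna_genotypes"], "expression", "simulate")
    params = dict(params or {})
    counts = io.read_tsv(_path(outdir, "rna_counts"))
    genotypes = io.read_tsv(_path(outdir, "rna_genotypes"))
    informative = allelexpr.find_informative_alleles(genotypes)
    records = allelexpr.per_copy_expression(
        counts, informative, min_reads=int(params.get("min_reads", allelexpr.DEFAULT_MIN_READS))
    )
    io.write_tsv(records, _path(outdir, "expression"))
    compare = {}
    for other in ("cancer", "host"):
        try:
            res = allelexpr.compare_sources(records, "HT", other)
            compare[f"HT_vs_{other}"] = asdict(res)
        except ValueError as exc:
            compare[f"HT_vs_{other}"] = {"error": str(exc)}
    io.write_json(compare, _path(outdir, "expression_compare"))
    return records


STAGES = {
    "simulate": (stage_simulate, [], ["samples", "sites", "ad_ref", "ad_alt", "cn", "junctions",
                                      "bins", "counts_all", "counts_cpg", "mut_events",
                                      "rna_counts", "rna_genotypes", "truth"]),
    "genotype": (stage_genotype, ["samples", "sites", "ad_ref", "ad_alt", "cn"],
                 ["states", "alt_copies", "consensus", "screened"]),
    "screen": (stage_screen, ["states", "consensus", "screened"],
               ["flips", "window_stats", "regions", "carriers"]),
    "hallmarks": (stage_hallmarks, ["regions", "carriers", "cn", "mut_events", "bins", "counts_all"],
                  ["hallmarks"]),
    "chain": (stage_chain, ["carriers", "cn", "junctions"], ["chain", "chain_summary"]),
    "date": (stage_date, ["carriers", "cn", "bins", "counts_cpg"], ["clock"]),
    "haplotype": (stage_haplotype, ["carriers", "samples", "sites", "ad_ref", "ad_alt", "cn"],
                  ["ht_genotypes"]),
    "expression": (stage_expression, ["rna_counts", "rna_genotypes"], ["expression", "expression_compare"]),
}
STAGE_ORDER = list(STAGES)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, outdir, stages=None, seed: int | None = None, log=None) -> dict:
    """Run the requested stages in dependency order; returns the manifest.

    ``config`` maps stage names to their parameter dicts (plus a top-level
    ``seed``).  Stage subsets are allowed as long as upstream outputs exist.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = dict(config or {})
    seed = seed if seed is not None else config.get("seed")
    requested = list(stages) if stages else STAGE_ORDER
    unknown = [s for s in requested if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}")

    manifest = {
        "version": __version__,
        "seed": seed,
        "config_digest": hashlib.sha256(repr(sorted(config.items())).encode()).hexdigest(),
        "stages": [],
    }
    for name in STAGE_ORDER:
        if name not in requested:
            continue
        fn, inputs, outputs = STAGES[name]
        in_digests = {
            FILES[k]: _digest(_path(outdir, k)) for k in inputs if _path(outdir, k).exists()
        }
        if name == "simulate":
            fn(outdir, config.get("simulate"), seed=seed)
        else:
            fn(outdir, config.get(name))
        out_digests = {
            FILES[k]: _digest(_path(outdir, k)) for k in outputs if _path(outdir, k).exists()
        }
        manifest["stages"].append({"name": name, "inputs": in_digests, "outputs": out_digests})
        if log is not None:
            log(f"stage {name}: done")
        if name == "screen" and log is not None:
            carriers = io.read_json(_path(outdir, "carriers"))["carrier_ids"]
            if not carriers:
                log(NO_TRANSFER_MESSAGE)
    io.write_json(manifest, outdir / "manifest.json")
    return manifest
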