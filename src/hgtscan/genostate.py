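"""Purity-corrected genotype-state calling at germline SNPs.

A transmissible-cancer biopsy is a mixture of cancer cells (fraction ``p``,
the tumor purity) and infiltrating cells from the current host animal.  At a
biallelic SNP the expected alternate-read fraction of the mixture is

    q(k) = (p * k + (1 - p) * h) / (p * c + 2 * (1 - p))

where ``k`` is the number of cancer chromosome copies carrying the alternate
allele, ``c`` the total cancer copy number at the locus, and ``h`` the number
of alternate copies in the (diploid) host genome.  Genotype states are called
by maximising the binomial likelihood of the observed read counts over the
discrete dosages ``k = 0..c``; a site is heterozygous in the cancer exactly
when ``0 < k < c``.  Lineage-level consensus states (the reference the
flipping-SNP screen compares against) are strict majorities of the per-tumor
hom/het calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

# per-tumor genotype state codes
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = 3
STATE_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}

# lineage consensus codes
CONS_HOM = 0
CONS_HET = 1
CONS_UNDETERMINED = 2
CONSENSUS_NAMES = {CONS_HOM: "hom", CONS_HET: "het", CONS_UNDETERMINED: "undetermined"}

DEFAULT_MIN_DEPTH = 15
DEFAULT_MIN_CALL_FRACTION = 0.8

_EPS = 1e-9


@dataclass(frozen=True)
class GenotypeCall:
    """Genotype call at one site in one tumor.

    ``confidence`` is the log-likelihood ratio between the best and the
    second-best allele dosage; ``reason`` explains a missing call.
    """

    state: str
    alt_copies: int
    total_cn: int
    confidence: float
    reason: str | None = None


def mixture_alt_fraction(alt_copies, total_cn, purity, host_alt_copies):
    """Expected alternate-read fraction of a tumor/host mixture.

    All arguments broadcast; ``host_alt_copies`` counts alternate alleles of
    the diploid host (0, 1 or 2).
    """
    k = np.asarray(alt_copies, dtype=float)
    c = np.asarray(total_cn, dtype=float)
    p = np.asarray(purity, dtype=float)
    h = np.asarray(host_alt_copies, dtype=float)
    return (p * k + (1.0 - p) * h) / (p * c + 2.0 * (1.0 - p))


def correct_vaf(vaf_obs, purity, tumor_cn, host_dosage_fraction=0.0):
    """Invert the mixture model: observed VAF -> cancer-cell allele fraction.

    ``host_dosage_fraction`` is the host alternate-allele fraction g_h in
    {0, 0.5, 1}.  Returns (vaf * D - 2*(1-p)*g_h) / (p * c) with
    D = p*c + 2*(1-p), clamped to [0, 1].  NaN inputs (depth-0 sites)
    propagate as NaN.
    """
    p = np.asarray(purity, dtype=float)
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ConfigError("purity must lie in (0, 1]")
    c = np.asarray(tumor_cn, dtype=float)
    if np.any(c < 1):
        raise ConfigError("tumor_cn must be >= 1")
    g = np.asarray(host_dosage_fraction, dtype=float)
    v = np.asarray(vaf_obs, dtype=float)
    denom = p * c + 2.0 * (1.0 - p)
    out = (v * denom - 2.0 * (1.0 - p) * g) / (p * c)
    out = np.clip(out, 0.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def host_dosage_fractions(host_ref, host_alt, min_depth: int = DEFAULT_MIN_DEPTH):
    """Estimate host alternate-allele fractions from host read counts.

    Hosts are assumed diploid, so the fraction is 2*VAF rounded to the
    nearest of {0, 0.5, 1}.  Sites below ``min_depth`` return NaN and are
    treated as missing downstream.
    """
    r = np.asarray(host_ref, dtype=float)
    a = np.asarray(host_alt, dtype=float)
    depth = r + a
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, a / np.maximum(depth, 1), np.nan)
    g = np.clip(np.round(2.0 * vaf) / 2.0, 0.0, 1.0)
    return np.where(depth >= min_depth, g, np.nan)


def classify_genotypes(
    ref_reads,
    alt_reads,
    purity,
    tumor_cn,
    host_dosage_fraction=0.0,
    min_depth: int = DEFAULT_MIN_DEPTH,
):
    """Vectorised maximum-likelihood genotype classification.

    Parameters broadcast to a common shape (typically sites x tumors).
    ``tumor_cn`` is the integer total copy number per entry; entries with
    cn < 2 (outside the screen's remit), depth < ``min_depth`` or an
    unresolvable host dosage (NaN) are returned as MISSING.

    Returns ``(alt_copies, state, confidence)`` arrays; confidence is the
    log-likelihood gap between the two best dosages (NaN where missing).
    """
    ref = np.asarray(ref_reads)
    alt = np.asarray(alt_reads)
    p = np.asarray(purity, dtype=float)
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ConfigError("purity must lie in (0, 1]")
    c = np.asarray(tumor_cn)
    g = np.asarray(host_dosage_fraction, dtype=float)

    ref, alt, p, c, g = np.broadcast_arrays(ref, alt, p, c, g)
    shape = ref.shape
    ref, alt, p, c, g = (np.ravel(a) for a in (ref, alt, p, c, g))
    depth = ref + alt
    c_int = c.astype(np.int64)
    host_alt = 2.0 * g  # host alternate copies
    host_missing = np.isnan(host_alt)

    alt_f = alt.astype(float)
    ref_f = ref.astype(float)
    denom = p * c_int + 2.0 * (1.0 - p)
    hterm = (1.0 - p) * np.where(host_missing, 0.0, host_alt)

    kmax = int(c_int.max(initial=2))
    best = np.full(depth.shape, -np.inf)
    second = np.full(depth.shape, -np.inf)
    k_hat = np.zeros(depth.shape, dtype=np.int64)
    for k in range(kmax + 1):
        q = np.clip((p * k + hterm) / denom, _EPS, 1.0 - _EPS)
        # binomial log-likelihood up to the k-independent log C(n, alt) term,
        # which cancels in every argmax and likelihood-ratio below
        lk = alt_f * np.log(q) + ref_f * np.log1p(-q)
        lk[k > c_int] = -np.inf
        upd = lk > best
        second = np.where(upd, best, np.maximum(second, lk))
        k_hat = np.where(upd, k, k_hat)
        best = np.where(upd, lk, best)
    confidence = best - second

    state = np.full(depth.shape, HET, dtype=np.int8)
    state[k_hat == 0] = HOM_REF
    state[k_hat == c_int] = HOM_ALT

    missing = (depth < min_depth) | (c_int < 2) | host_missing
    state = np.where(missing, MISSING, state).astype(np.int8)
    k_hat = np.where(missing, -1, k_hat)
    confidence = np.where(missing, np.nan, confidence)
    return k_hat.reshape(shape), state.reshape(shape), confidence.reshape(shape)


def classify_genotype(
    ref_reads: int,
    alt_reads: int,
    purity: float,
    tumor_cn: int,
    host_dosage_fraction: float = 0.0,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> GenotypeCall:
    """Scalar convenience wrapper around :func:`classify_genotypes`."""
    k, state, conf = classify_genotypes(
        ref_reads, alt_reads, purity, tumor_cn, host_dosage_fraction, min_depth
    )
    k = int(np.asarray(k))
    state = int(np.asarray(state))
    conf = float(np.asarray(conf))
    reason = None
    if state == MISSING:
        if int(tumor_cn) < 2:
            reason = "copy number below 2: site excluded from the screen"
        elif ref_reads + alt_reads < min_depth:
            reason = f"depth below minimum ({min_depth})"
        else:
            reason = "host dosage unresolved"
    return GenotypeCall(STATE_NAMES[state], k, int(tumor_cn), conf, reason)


def consensus_states(
    states: np.ndarray,
    min_call_fraction: float = DEFAULT_MIN_CALL_FRACTION,
) -> np.ndarray:
    """Per-site lineage consensus from a sites x tumors state matrix.

    A site is consensus-hom (hom_ref or hom_alt) or consensus-het by strict
    majority of the non-missing calls.  Ties, and sites where fewer than
    ``min_call_fraction`` of the tumors have non-missing calls, are
    undetermined.
    """
    st = np.asarray(states)
    if st.ndim == 1:
        st = st[:, None]
    n = st.shape[1]
    hom = ((st == HOM_REF) | (st == HOM_ALT)).sum(axis=1)
    het = (st == HET).sum(axis=1)
    called = hom + het
    cons = np.full(st.shape[0], CONS_UNDETERMINED, dtype=np.int8)
    ok = called >= min_call_fraction * n
    cons[ok & (hom > het)] = CONS_HOM
    cons[ok & (het > hom)] = CONS_HET
    return cons


def consensus_state(states, min_call_fraction: float = DEFAULT_MIN_CALL_FRACTION) -> str:
    """Consensus over one site's calls; returns 'hom'/'het'/'undetermined'."""
    arr = np.asarray(
        [s if isinstance(s, (int, np.integer)) else _STATE_CODES[s] for s in states],
        dtype=np.int8,
    )
    code = consensus_states(arr.reshape(1, -1), min_call_fraction)
    return CONSENSUS_NAMES[int(code[0])]


_STATE_CODES = {v: k for k, v in STATE_NAMES.items()}
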