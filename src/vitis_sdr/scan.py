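"""Sex-linked SNP discovery from genotype panels.

In a dioecious panel every female is homozygous for the f allele and
every male heterozygous at a fully sex-linked site, which leaves three
population-genetic fingerprints: an elevated minor allele frequency
(n_males / 2N), a strong excess of heterozygotes relative to
Hardy-Weinberg equilibrium, and complete linkage disequilibrium across
the region.  This module computes those statistics, flags cosegregating
sites, and turns a flagged set into SDR boundary estimates.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import gammaln

MISSING = -1


def site_maf(genotypes: Iterable[int]) -> float:
    """Minor allele frequency of one site over non-missing diploid calls.

    ``genotypes`` are M-allele dosages (0/1/2); -1 marks missing.
    """
    g = np.asarray(genotypes)
    g = g[g >= 0]
    if g.size == 0:
        raise ValueError("site has no non-missing genotypes")
    p_alt = g.sum() / (2 * g.size)
    return float(min(p_alt, 1.0 - p_alt))


def hwe_exact(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Two-sided exact test for departure from Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and enumerates every
    heterozygote count of compatible parity, summing the probabilities of
    all configurations no more probable than the observed one (the
    standard "sum of less-or-equally-probable tables" rule, no mid-p
    correction).  Monomorphic sites return 1.
    """
    counts = (n_homref, n_het, n_homalt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotype is required")
    n_alt = 2 * n_homalt + n_het
    n_ref = 2 * n_homref + n_het
    n_rare = min(n_ref, n_alt)
    if n_rare == 0:
        return 1.0

    ks = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - ks) // 2
    hom_common = n - ks - hom_rare
    # conditional distribution: P(k) = n! 2^k n_rare! n_common! / (hr! k! hc! (2n)!)
    n_common = 2 * n - n_rare
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(ks + 1)
        - gammaln(hom_common + 1)
        + ks * math.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(n_common + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[ks == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def ld_r2(dosage_a: Iterable[int], dosage_b: Iterable[int]) -> float:
    """Composite LD between two sites: squared correlation of dosages.

    Computed over samples non-missing at both sites; unphased genotype
    dosages stand in for haplotype counts.  Returns NaN when either site
    is monomorphic among the shared samples.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    mask = (a >= 0) & (b >= 0)
    a, b = a[mask], b[mask]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_matrix(genotypes: np.ndarray, positions: Iterable[int]) -> pd.DataFrame:
    """Pairwise r^2 in long format (pos_a, pos_b, r2) for a site block."""
    pos = np.asarray(positions)
    n_sites = genotypes.shape[1]
    if pos.size != n_sites:
        raise ValueError("positions length must match genotype columns")
    rows = []
    for i in range(n_sites):
        for j in range(i, n_sites):
            rows.append((int(pos[i]), int(pos[j]), ld_r2(genotypes[:, i], genotypes[:, j])))
    return pd.DataFrame(rows, columns=["pos_a", "pos_b", "r2"])


def cosegregation_scan(
    genotypes: np.ndarray,
    positions: Iterable[int],
    sex_labels: Iterable[str],
    max_mismatch_frac: float = 0.02,
) -> pd.DataFrame:
    """Per-site statistics and sex-linkage flags for a dioecious panel.

    ``sex_labels`` must be 'female' or 'male' per accession (wild-panel
    semantics: females f/f hence homozygous reference, males M/f hence
    heterozygous at sex-linked sites); accessions with any other label
    are excluded.  A site is flagged sex-linked when the fraction of
    accessions violating that expectation, among non-missing calls, is at
    most ``max_mismatch_frac``.

    Returns a DataFrame with columns pos, maf, hwe_p, neg_log10_hwe_p,
    coseg_mismatches, n_called, sex_linked.
    """
    labels = np.asarray(list(sex_labels))
    keep = np.isin(labels, ("female", "male"))
    g = np.asarray(genotypes)[keep]
    labels = labels[keep]
    is_female = labels == "female"
    is_male = labels == "male"
    if is_female.sum() < 2 or is_male.sum() < 2:
        raise ValueError("need at least 2 accessions of each sex")
    pos = np.asarray(list(positions))
    if pos.size != g.shape[1]:
        raise ValueError("positions length must match genotype columns")

    observed = g >= 0
    n_called = observed.sum(axis=0)
    mism_f = ((g != 0) & observed & is_female[:, None]).sum(axis=0)
    mism_m = ((g != 1) & observed & is_male[:, None]).sum(axis=0)
    mismatches = mism_f + mism_m
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_called > 0, mismatches / np.maximum(n_called, 1), 1.0)
    flagged = (n_called > 0) & (frac <= max_mismatch_frac)

    mafs = np.empty(pos.size)
    hwe_ps = np.empty(pos.size)
    for j in range(pos.size):
        col = g[:, j]
        col = col[col >= 0]
        if col.size == 0:
            mafs[j] = np.nan
            hwe_ps[j] = 1.0
            continue
        mafs[j] = site_maf(col)
        hwe_ps[j] = hwe_exact(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )

    return pd.DataFrame(
        {
            "pos": pos,
            "maf": mafs,
            "hwe_p": hwe_ps,
            "neg_log10_hwe_p": -np.log10(hwe_ps),
            "coseg_mismatches": mismatches,
            "n_called": n_called,
            "sex_linked": flagged,
        }
    )


def sdr_boundaries(
    flagged_positions: Iterable[int], max_gap_bp: int = 10_000
) -> tuple[int, int] | None:
    """Smallest interval covering the largest gap-limited run of flagged sites.

    Flagged positions are clustered greedily: a new cluster starts
    whenever the gap to the previous site exceeds ``max_gap_bp``.  The
    cluster with the most sites wins (ties: the longer span, then the
    lower coordinate); its first and last site delimit the interval.
    Returns ``None`` when no site is flagged.
    """
    pos = np.sort(np.asarray(list(flagged_positions), dtype=int))
    if pos.size == 0:
        return None
    breaks = np.flatnonzero(np.diff(pos) > max_gap_bp)
    clusters = np.split(pos, breaks + 1)
    best = max(clusters, key=lambda c: (c.size, c[-1] - c[0], -c[0]))
    return int(best[0]), int(best[-1])
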