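"""Allele-specific expression association with flower-sex factors.

For every polymorphic transcribed site the M-allele read fraction is
compared between samples grouped by a binary flower-sex factor (by
default female-sterile versus not).  The statistic is the difference in
group mean allele fractions and the p-value comes from a label
permutation test with the add-one rule, which keeps the test valid at
the small sample sizes typical of these panels.  Benjamini-Hochberg
q-values flag sites across the scan; raw p-values are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .simulate import AseCountTable


@dataclass(frozen=True)
class AseResult:
    """Permutation-test outcome for one transcribed site."""

    stat: float
    p_value: float
    neg_log10_p: float
    n_group1: int
    n_group0: int
    mean_frac_group1: float
    mean_frac_group0: float


def ase_site_test(
    ref_counts: Iterable[int],
    alt_counts: Iterable[int],
    groups: Iterable[bool],
    min_depth: int = 10,
    n_perm: int = 10_000,
    seed: int = 0,
) -> AseResult:
    """Permutation test of allele-fraction difference between two groups.

    Samples with total depth below ``min_depth`` are dropped; the
    observed statistic is mean(alt fraction | group) - mean(alt fraction
    | other), and the two-sided p-value is (1 + #{|perm| >= |obs|}) /
    (1 + n_perm) over ``n_perm`` seeded label permutations.
    """
    ref = np.asarray(list(ref_counts) if not isinstance(ref_counts, np.ndarray) else ref_counts)
    alt = np.asarray(list(alt_counts) if not isinstance(alt_counts, np.ndarray) else alt_counts)
    grp = np.asarray(list(groups) if not isinstance(groups, np.ndarray) else groups, dtype=bool)
    if not (ref.shape == alt.shape == grp.shape):
        raise ValueError("ref, alt and groups must have equal length")
    depth = ref + alt
    keep = depth >= min_depth
    ref, alt, grp, depth = ref[keep], alt[keep], grp[keep], depth[keep]
    n1 = int(grp.sum())
    n0 = int((~grp).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("a group is empty after depth filtering")

    frac = alt / depth
    obs = float(frac[grp].mean() - frac[~grp].mean())

    rng = np.random.default_rng(seed)
    n = frac.size
    total = frac.sum()
    # permute labels: random n1-subsets as group 1
    ranks = rng.random((n_perm, n)).argsort(axis=1)
    sel = ranks < n1
    s1 = np.where(sel, frac[None, :], 0.0).sum(axis=1)
    stats = s1 / n1 - (total - s1) / n0
    n_extreme = int((np.abs(stats) >= abs(obs) - 1e-12).sum())
    p = (1 + n_extreme) / (1 + n_perm)

    return AseResult(
        stat=obs,
        p_value=p,
        neg_log10_p=float(-np.log10(p)),
        n_group1=n1,
        n_group0=n0,
        mean_frac_group1=float(frac[grp].mean()),
        mean_frac_group0=float(frac[~grp].mean()),
    )


def ase_scan(
    table: AseCountTable,
    factor: str = "female_sterile",
    min_depth: int = 10,
    n_perm: int = 10_000,
    seed: int = 0,
    min_group: int = 2,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the site test across a whole ASE count table.

    Sites where either factor group retains fewer than ``min_group``
    samples after depth filtering are skipped.  Adds Benjamini-Hochberg
    q-values and a significance flag at ``fdr_alpha``.
    """
    if factor not in table.factors.columns:
        raise ValueError(f"unknown phenotype factor {factor!r}")
    grp = table.factors[factor].to_numpy(dtype=bool)
    rows = []
    for j in range(table.positions.size):
        depth = table.ref[:, j] + table.alt[:, j]
        keep = depth >= min_depth
        if grp[keep].sum() < min_group or (~grp[keep]).sum() < min_group:
            continue
        res = ase_site_test(
            table.ref[:, j], table.alt[:, j], grp,
            min_depth=min_depth, n_perm=n_perm, seed=seed + j,
        )
        rows.append(
            {
                "pos": int(table.positions[j]),
                "gene": table.genes[j],
                "stat": res.stat,
                "p_value": res.p_value,
                "neg_log10_p": res.neg_log10_p,
                "n_group1": res.n_group1,
                "n_group0": res.n_group0,
            }
        )
    results = pd.DataFrame(rows)
    if len(results):
        results["q_value"] = false_discovery_control(results["p_value"], method="bh")
        results["significant"] = results["q_value"] <= fdr_alpha
    return results


def rank_sites(results: pd.DataFrame) -> pd.DataFrame:
    """Order scan results by association strength (ties by position)."""
    if results.empty:
        raise ValueError("no results to rank")
    return results.sort_values(
        ["neg_log10_p", "pos"], ascending=[False, True], ignore_index=True
    )
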