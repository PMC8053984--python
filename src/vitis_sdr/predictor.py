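"""Flower-sex prediction from read-level allele depths.

The predictor calls each SDR region's numeric state by Bayes-factor model
comparison: for every site the read counts are scored under three
binomial models of the M-allele read fraction - homozygous f
(``base_error``), heterozygous (0.5) and homozygous M (``1 -
base_error``) - and the site log-likelihoods are summed over the region
(sites are treated as independent, so the region log Bayes factor is the
sum of site contributions).  The best model is called when it beats both
rivals by at least ``bf_threshold`` in log Bayes factor.

Phenotype follows from the two-factor decomposition of flower sex:
female-sterile iff region A carries an M allele, male-sterile iff region
C carries none; the full A-D numeric vector identifies the haplotype
combination.  The module also genotypes the VviINP1 8 bp indel marker,
whose homozygous deletion implies male sterility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import (
    INP1_INTACT_SEQ,
    INP1_MOTIF,
    REGIONS,
    SDRModel,
)
from .painting import classify_genotype
from .simulate import AlleleDepthTable

#: default decision threshold on the log Bayes factor (ln 100)
LOG_BF_THRESHOLD = math.log(100.0)


def site_log_likelihoods(ref_count, alt_count, base_error: float):
    """Log-likelihood of (ref, alt) read counts under the three models.

    Returns (hom_f, het, hom_M).  The binomial coefficient is omitted -
    it cancels in every Bayes factor.  Zero-depth sites contribute 0 to
    all three models (uninformative).
    """
    if not (0.0 < base_error < 0.5):
        raise ValueError("base_error must lie in (0, 0.5)")
    ref = np.asarray(ref_count, dtype=float)
    alt = np.asarray(alt_count, dtype=float)
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("read counts must be non-negative")
    log_e = math.log(base_error)
    log_1me = math.log(1.0 - base_error)
    l_hom_f = ref * log_1me + alt * log_e
    l_het = (ref + alt) * math.log(0.5)
    l_hom_m = ref * log_e + alt * log_1me
    return l_hom_f, l_het, l_hom_m


@dataclass(frozen=True)
class RegionBF:
    """Bayes-factor evidence and call for one region.

    ``loglik`` holds the summed log-likelihoods of the hom-f, het and
    hom-M models; ``call`` is the winning state (0/1/2) or None when the
    winner's smallest pairwise log Bayes factor falls below threshold or
    no site passed filtering.
    """

    region: str
    loglik: tuple[float, float, float]
    n_sites: int
    call: int | None
    min_log_bf: float


def region_bayes_factor(
    ref_counts: Iterable[int],
    alt_counts: Iterable[int],
    base_error: float = 0.01,
    min_depth: int = 3,
    bf_threshold: float = LOG_BF_THRESHOLD,
    region: str = "",
) -> RegionBF:
    """Call one region's numeric state from its sites' read counts.

    Sites with total depth below ``min_depth`` are discarded; the
    remaining site log-likelihoods are summed per model and the maximal
    model is called when its log Bayes factor against both alternatives
    reaches ``bf_threshold``.  No qualifying site yields a no-call.
    """
    ref = np.asarray(list(ref_counts) if not isinstance(ref_counts, np.ndarray) else ref_counts)
    alt = np.asarray(list(alt_counts) if not isinstance(alt_counts, np.ndarray) else alt_counts)
    if ref.shape != alt.shape:
        raise ValueError("ref and alt count vectors must have equal length")
    keep = (ref + alt) >= min_depth
    n = int(keep.sum())
    if n == 0:
        return RegionBF(region, (0.0, 0.0, 0.0), 0, None, float("nan"))
    l0, l1, l2 = site_log_likelihoods(ref[keep], alt[keep], base_error)
    totals = np.array([l0.sum(), l1.sum(), l2.sum()])
    best = int(totals.argmax())
    others = np.delete(totals, best)
    min_log_bf = float(totals[best] - others.max())
    call = best if min_log_bf >= bf_threshold else None
    return RegionBF(region, tuple(totals), n, call, min_log_bf)


def predict_phenotype(region_calls: Mapping[str, int | None]) -> tuple[str, str]:
    """Phenotype and class label from per-region numeric calls.

    Regions A and C must be called.  Female-sterile iff A is 1 or 2;
    male-sterile iff C is 0; the phenotype follows from the two factors
    (both sterile is impossible for any haplotype pair and reported as
    'inconsistent').  The class label is the signature match on the full
    A-D vector, 'unknown' when fewer than 3 regions are called or no
    unique signature fits.
    """
    calls = {r: region_calls.get(r) for r in REGIONS}
    if calls["A"] is None or calls["C"] is None:
        raise ValueError("phenotype prediction requires called A and C regions")
    female_sterile = calls["A"] in (1, 2)
    male_sterile = calls["C"] == 0
    if female_sterile and male_sterile:
        phenotype = "inconsistent"
    elif female_sterile:
        phenotype = "male"
    elif male_sterile:
        phenotype = "female"
    else:
        phenotype = "hermaphrodite"
    vector = tuple(calls[r] for r in REGIONS)
    try:
        label = classify_genotype(vector)
    except ValueError:
        label = "unknown"
    return phenotype, label


def rna_excluded_genes(effect_spec: Mapping[str, Mapping[str, float]]) -> list[str]:
    """Genes with monoallelic expression in any group, to drop from RNA calls.

    A gene whose M-allele multiplier differs from 1 in any phenotype
    group expresses its alleles unevenly; its sites would bias the
    binomial genotype models and are excluded before summation.
    """
    return [
        gene
        for gene, spec in effect_spec.items()
        if any(float(m) != 1.0 for m in spec.values())
    ]


@dataclass(eq=False)
class SamplePrediction:
    """Region calls, numeric vector, class label and phenotype for one sample."""

    sample: str
    region_bfs: dict[str, RegionBF]
    numeric: tuple[int | None, ...]
    class_label: str
    phenotype: str

    def to_dict(self) -> dict:
        return {
            "sample": self.sample,
            "regions": {
                r: {
                    "call": bf.call,
                    "n_sites": bf.n_sites,
                    "min_log_bf": None if math.isnan(bf.min_log_bf) else bf.min_log_bf,
                }
                for r, bf in self.region_bfs.items()
            },
            "numeric": list(self.numeric),
            "class": self.class_label,
            "phenotype": self.phenotype,
        }


def predict_sample(
    positions: np.ndarray,
    ref: np.ndarray,
    alt: np.ndarray,
    model: SDRModel,
    sample: str = "",
    base_error: float = 0.01,
    min_depth: int = 3,
    bf_threshold: float = LOG_BF_THRESHOLD,
    exclude_genes: Sequence[str] = (),
) -> SamplePrediction:
    """Predict one sample from its per-site allele depths.

    ``positions``/``ref``/``alt`` are parallel vectors; sites are matched
    to the model's region call sets by position.  ``exclude_genes`` drops
    sites inside the named genes (the RNA monoallelic-expression rule,
    see :func:`rna_excluded_genes`).
    """
    pos = np.asarray(positions)
    excluded = np.zeros(model.positions.size, dtype=bool)
    if len(exclude_genes):
        genes = model.gene_of(model.positions)
        excluded = np.isin(genes.astype(str), list(exclude_genes))

    pos_index = {int(p): i for i, p in enumerate(pos)}
    region_bfs: dict[str, RegionBF] = {}
    for region in REGIONS:
        mask = model.region_call_mask(region) & ~excluded
        wanted = model.positions[mask]
        idx = [pos_index[int(p)] for p in wanted if int(p) in pos_index]
        region_bfs[region] = region_bayes_factor(
            ref[idx], alt[idx], base_error=base_error, min_depth=min_depth,
            bf_threshold=bf_threshold, region=region,
        )

    calls = {r: bf.call for r, bf in region_bfs.items()}
    numeric = tuple(calls[r] for r in REGIONS)
    try:
        phenotype, label = predict_phenotype(calls)
    except ValueError:
        phenotype, label = "no-call", "unknown"
    return SamplePrediction(
        sample=sample, region_bfs=region_bfs, numeric=numeric,
        class_label=label, phenotype=phenotype,
    )


def predict_panel(
    table: AlleleDepthTable,
    model: SDRModel,
    base_error: float = 0.01,
    min_depth: int = 3,
    bf_threshold: float = LOG_BF_THRESHOLD,
    exclude_genes: Sequence[str] = (),
) -> list[SamplePrediction]:
    """Predict every sample in an allele-depth table."""
    return [
        predict_sample(
            table.positions,
            table.ref[i],
            table.alt[i],
            model,
            sample=name,
            base_error=base_error,
            min_depth=min_depth,
            bf_threshold=bf_threshold,
            exclude_genes=exclude_genes,
        )
        for i, name in enumerate(table.samples)
    ]


@dataclass(frozen=True)
class Inp1MarkerCall:
    """Diploid state of the VviINP1 8 bp indel marker.

    ``alleles`` is the unordered pair of allele states; the marker
    implies male sterility exactly when both copies are deleted.
    """

    alleles: tuple[str, str]

    @property
    def male_sterile(self) -> bool:
        return self.alleles == ("deleted", "deleted")


def _allele_from_length(length: int, intact_length: int, tolerance: int = 2) -> str:
    d_intact = abs(length - intact_length)
    d_deleted = abs(length - (intact_length - 8))
    if min(d_intact, d_deleted) > tolerance:
        raise ValueError(
            f"read-length mode {length} matches neither the intact ({intact_length}) "
            f"nor the deleted ({intact_length - 8}) allele"
        )
    return "intact" if d_intact <= d_deleted else "deleted"


def inp1_indel_genotype(
    allele_sequences: Sequence[str] | None = None,
    spanning_read_lengths: Iterable[int] | None = None,
    intact_length: int | None = None,
    motif: str = INP1_MOTIF,
    min_mode_frac: float = 0.1,
) -> Inp1MarkerCall:
    """Genotype the INP1 indel from allele sequences or spanning reads.

    Provide either two resolved allele sequences (an allele is deleted
    when it lacks the 8 bp motif) or a collection of lengths of reads
    spanning the indel.  Read-length modes carrying at least
    ``min_mode_frac`` of the reads are mapped to the intact or deleted
    allele length (difference 8); a single mode is a homozygote, two
    modes a heterozygote, and modes matching neither allele length raise.
    """
    if (allele_sequences is None) == (spanning_read_lengths is None):
        raise ValueError("provide exactly one of allele_sequences or spanning_read_lengths")

    if allele_sequences is not None:
        if len(allele_sequences) != 2:
            raise ValueError("expected exactly two allele sequences")
        states = tuple(
            sorted("intact" if motif in seq else "deleted" for seq in allele_sequences)
        )
        return Inp1MarkerCall(alleles=states)

    lengths = np.asarray(list(spanning_read_lengths), dtype=int)
    if lengths.size == 0:
        raise ValueError("no spanning reads provided")
    if intact_length is None:
        intact_length = len(INP1_INTACT_SEQ)
    values, counts = np.unique(lengths, return_counts=True)
    keep = counts >= max(1, math.ceil(min_mode_frac * lengths.size))
    values, counts = values[keep], counts[keep]
    if values.size == 0:
        raise ValueError("no read-length mode passes the frequency threshold")
    order = np.argsort(counts)[::-1]
    modes = values[order][:2]
    states = sorted({_allele_from_length(int(m), intact_length) for m in modes})
    if len(states) == 1:
        states = states * 2
    return Inp1MarkerCall(alleles=tuple(states))


def male_sterility_from_markers(
    inp1_call: Inp1MarkerCall, c_region_call: int | None
) -> bool | None:
    """Combine the INP1 indel marker with the linked C-region state.

    The indel and the C-region numeric call are redundant readouts of the
    male-sterility factor (C = 0 means no intact INP1 copy).  Concordant
    evidence returns the male-sterility status; a discordant pair returns
    None.  Without a C-region call the indel marker decides alone.
    """
    ms_indel = inp1_call.male_sterile
    if c_region_call is None:
        return ms_indel
    ms_c = c_region_call == 0
    return ms_indel if ms_indel == ms_c else None
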