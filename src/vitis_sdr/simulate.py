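"""Synthetic data generators for the SDR toolkit.

The generators emulate the study designs the downstream modules analyse:

* diploid genotype panels composed from the f/M/H1/H2 haplotype templates
  (wild panels: females f/f, males M/f; cultivated panels add H carriers),
  with symmetric genotyping error and missingness;
* per-site allele read depths (DNA shotgun, or RNA with per-gene
  expression masking for allele-specific effects);
* windowed unique-mapping depth tracks for female and male bulk pools of
  13 accessions each, mapped against the two haplotype assemblies;
* allele-specific expression count tables;
* read-length evidence spanning the VviINP1 8 bp indel.

All functions are deterministic under their ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    CLASSES,
    INP1_DELETED_SEQ,
    INP1_INTACT_SEQ,
    SDRModel,
    class_haplotypes,
    phenotype_of,
)

POOLS = ("female-bulk", "male-bulk")
ASSEMBLIES = ("f-hap", "M-hap")

#: Default allele-specific expression effects: the M allele of VviYABBY3
#: is expressed in female-sterile (male-flowered) samples and silenced in
#: all others.  Values are M-allele expression multipliers relative to the
#: f allele; genes not listed are expressed biallelically (multiplier 1).
DEFAULT_EFFECT_SPEC: Mapping[str, Mapping[str, float]] = {
    "VviYABBY3": {"female_sterile": 1.0, "other": 0.0},
}


@dataclass(eq=False)
class GenotypePanel:
    """Per-accession, per-site diploid genotypes plus simulation truth.

    ``genotypes`` holds the observed M-allele dosage (0/1/2, -1 missing)
    after the error and missingness processes; ``truth_genotypes`` the
    error-free composition.  ``sites`` annotates every column with
    position, region ('A'..'D' or 'flank'), and kind ('sex_linked',
    'b_diagnostic' or 'neutral').
    """

    accessions: pd.DataFrame
    sites: pd.DataFrame
    genotypes: np.ndarray
    truth_genotypes: np.ndarray
    error_mask: np.ndarray
    missing_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def positions(self) -> np.ndarray:
        return self.sites["pos"].to_numpy()

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def sex_labels(self) -> np.ndarray:
        """'female'/'male' per accession; hermaphrodites map to ''."""
        pheno = self.accessions["phenotype"].to_numpy()
        return np.where(np.isin(pheno, ("female", "male")), pheno, "")


@dataclass(eq=False)
class AlleleDepthTable:
    """Reference/alternative read counts per sample and site.

    ``ref`` counts reads supporting the f allele, ``alt`` the M allele;
    shapes are (n_samples, n_sites).  ``source`` is 'DNA' or 'RNA'.
    """

    samples: list[str]
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    source: str = "DNA"

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt


@dataclass(eq=False)
class WindowDepthTrack:
    """Fixed-width windowed unique-mapping depth of one pool on one assembly."""

    assembly: str
    pool: str
    window: int
    starts: np.ndarray
    ends: np.ndarray
    raw: np.ndarray
    flank_mask: np.ndarray
    normalized: np.ndarray | None = None


@dataclass(eq=False)
class AseCountTable:
    """Allele-specific expression counts at transcribed polymorphic sites.

    Restricted to sites inside annotated genes.  ``factors`` carries the
    two flower-sex factors per sample (female_sterile, male_sterile).
    """

    samples: list[str]
    positions: np.ndarray
    genes: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    factors: pd.DataFrame


def _check_rate(name: str, value: float, upper: float = 1.0) -> None:
    if not (0.0 <= value < upper):
        raise ValueError(f"{name} must be in [0, {upper}), got {value}")


def simulate_panel(
    model: SDRModel,
    n_per_class: Mapping[str, int],
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    n_neutral: int = 150,
) -> GenotypePanel:
    """Simulate a diploid genotype panel composed from haplotype templates.

    ``n_per_class`` maps class labels (any subset of the 10 combinations,
    e.g. ``{"f/f": 10, "M/f": 10}``) to accession counts.  Each genotype
    is flipped to a uniformly chosen other state with probability
    ``error_rate`` and set missing with probability ``missing_rate``.

    ``n_neutral`` sites segregating independently of sex (Hardy-Weinberg
    draws at a random allele frequency) are added in the flanking regions
    as scan negatives.
    """
    if not n_per_class:
        raise ValueError("n_per_class must name at least one genotype class")
    unknown = set(n_per_class) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown genotype classes: {sorted(unknown)}")
    _check_rate("error_rate", error_rate)
    _check_rate("missing_rate", missing_rate)

    rng = np.random.default_rng(seed)

    acc_rows = []
    truth_rows = []
    for label in CLASSES:  # deterministic order regardless of dict order
        count = int(n_per_class.get(label, 0))
        if count < 0:
            raise ValueError(f"negative count for class {label}")
        if count == 0:
            continue
        hap_a, hap_b = class_haplotypes(label)
        dosage = model.compose_genotype(hap_a, hap_b)
        for i in range(count):
            acc_rows.append(
                {
                    "id": f"{label.replace('/', 'x')}_{i:03d}",
                    "hap_a": hap_a,
                    "hap_b": hap_b,
                    "class_label": label,
                    "phenotype": phenotype_of(hap_a, hap_b),
                }
            )
            truth_rows.append(dosage)
    accessions = pd.DataFrame(acc_rows)
    n_acc = len(accessions)
    truth_sdr = np.array(truth_rows, dtype=np.int8)

    # neutral flank sites: allele frequency per site, HWE genotype draws
    sites = model.sites[["pos", "region", "kind"]].copy()
    sites["sex_linked"] = model.sites["sex_linked"]
    if n_neutral > 0:
        left_lo, left_hi = model.flank_left
        right_lo, right_hi = model.flank_right
        flank_pool = np.concatenate(
            [np.arange(left_lo, left_hi), np.arange(right_lo, right_hi)]
        )
        neutral_pos = np.sort(rng.choice(flank_pool, size=n_neutral, replace=False))
        freqs = rng.uniform(0.05, 0.5, size=n_neutral)
        neutral_truth = rng.binomial(2, freqs[None, :], size=(n_acc, n_neutral)).astype(np.int8)
        neutral_sites = pd.DataFrame(
            {
                "pos": neutral_pos,
                "region": "flank",
                "kind": "neutral",
                "sex_linked": False,
            }
        )
        sites = pd.concat([sites, neutral_sites], ignore_index=True)
        truth = np.concatenate([truth_sdr, neutral_truth], axis=1)
    else:
        truth = truth_sdr

    order = np.argsort(sites["pos"].to_numpy(), kind="stable")
    sites = sites.iloc[order].reset_index(drop=True)
    truth = truth[:, order]

    genotypes = truth.copy()
    error_mask = rng.random(genotypes.shape) < error_rate
    if error_mask.any():
        # flip to one of the two other states with equal probability
        shift = rng.integers(1, 3, size=int(error_mask.sum()))
        genotypes[error_mask] = (genotypes[error_mask] + shift) % 3
    missing_mask = rng.random(genotypes.shape) < missing_rate
    genotypes[missing_mask] = -1

    return GenotypePanel(
        accessions=accessions,
        sites=sites,
        genotypes=genotypes,
        truth_genotypes=truth,
        error_mask=error_mask,
        missing_mask=missing_mask,
        meta={
            "seed": seed,
            "error_rate": error_rate,
            "missing_rate": missing_rate,
            "n_neutral": n_neutral,
            "chrom": model.chrom,
        },
    )


def _expression_multipliers(
    model: SDRModel,
    positions: np.ndarray,
    female_sterile: np.ndarray,
    effect_spec: Mapping[str, Mapping[str, float]],
) -> np.ndarray:
    """M-allele expression multiplier per (sample, site)."""
    genes = model.gene_of(positions)
    mult = np.ones((female_sterile.size, positions.size))
    for gene, spec in effect_spec.items():
        cols = genes == gene
        if not cols.any():
            continue
        m_fs = float(spec.get("female_sterile", 1.0))
        m_other = float(spec.get("other", 1.0))
        mult[np.ix_(female_sterile, cols)] = m_fs
        mult[np.ix_(~female_sterile, cols)] = m_other
    return mult


def simulate_allele_depths(
    panel: GenotypePanel,
    mean_depth: float = 20.0,
    base_error: float = 0.01,
    seed: int = 0,
    source: str = "DNA",
    model: SDRModel | None = None,
    effect_spec: Mapping[str, Mapping[str, float]] | None = None,
) -> AlleleDepthTable:
    """Simulate per-site read counts for every accession in a panel.

    Total depth is Poisson with mean ``mean_depth``; the alt (M-allele)
    count is binomial with success probability ``base_error`` for
    genotype 0, 0.5 for genotype 1 and ``1 - base_error`` for genotype 2.
    Counts are generated from the panel's observed genotypes; missing
    genotypes yield zero depth.

    For ``source='RNA'`` a model is required: sites outside annotated
    genes get zero depth, and per-gene M-allele expression multipliers
    from ``effect_spec`` (default :data:`DEFAULT_EFFECT_SPEC`) rescale
    both the expected depth and the allelic balance, emulating
    monoallelic expression.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    _check_rate("base_error", base_error, upper=0.5)
    if source not in ("DNA", "RNA"):
        raise ValueError("source must be 'DNA' or 'RNA'")
    if panel.truth_genotypes is None:
        raise ValueError("panel lacks simulation truth genotypes")

    rng = np.random.default_rng(seed)
    g = panel.genotypes.astype(float)
    observed = g >= 0
    g = np.where(observed, g, 0.0)

    if source == "RNA":
        if model is None:
            raise ValueError("RNA simulation requires the SDR model (gene map)")
        spec = DEFAULT_EFFECT_SPEC if effect_spec is None else effect_spec
        fs = (panel.accessions["phenotype"] == "male").to_numpy()
        mult = _expression_multipliers(model, panel.positions, fs, spec)
        in_gene = model.gene_of(panel.positions) != ""
        # expression weight of each allele copy: f copies weigh 1, M copies m
        weight = (2.0 - g) + g * mult
        lam = mean_depth * weight / 2.0
        lam[:, ~in_gene] = 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            p_alt = np.where(weight > 0, g * mult / np.where(weight > 0, weight, 1.0), 0.0)
    else:
        lam = np.full(g.shape, float(mean_depth))
        p_alt = g / 2.0

    lam = np.where(observed, lam, 0.0)
    depth = rng.poisson(lam)
    # sequencing error flips the supported allele with probability base_error
    p = p_alt * (1.0 - base_error) + (1.0 - p_alt) * base_error
    alt = rng.binomial(depth, p)
    return AlleleDepthTable(
        samples=list(panel.accessions["id"]),
        positions=panel.positions.copy(),
        ref=(depth - alt).astype(np.int64),
        alt=alt.astype(np.int64),
        source=source,
    )


def _window_grid(length: int, window: int) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, length, window)
    ends = np.minimum(starts + window, length)
    return starts, ends


def simulate_bulk_depths(
    model: SDRModel,
    n_female: int = 13,
    n_male: int = 13,
    unit_coverage: float = 30.0,
    window: int = 500,
    seed: int = 0,
) -> dict[tuple[str, str], WindowDepthTrack]:
    """Simulate windowed unique-mapping depth for the two bulk pools.

    Returns tracks keyed by (pool, assembly).  ``unit_coverage`` is the
    raw depth corresponding to one haploid mapping unit; expected units
    inside the SDR are female-bulk 2 on the f assembly and 0 on the M
    assembly (f/f accessions contribute no M-haplotype reads), male-bulk
    1 on each, and 2 in the shared flanks for both pools.  Window counts
    are Poisson.
    """
    if n_female < 1 or n_male < 1:
        raise ValueError("pool sizes must be >= 1")
    if window <= 0:
        raise ValueError("window width must be positive")

    rng = np.random.default_rng(seed)
    sdr_units = {
        ("female-bulk", "f-hap"): 2.0,
        ("female-bulk", "M-hap"): 0.0,
        ("male-bulk", "f-hap"): 1.0,
        ("male-bulk", "M-hap"): 1.0,
    }
    flank_units = 2.0
    lengths = {
        "f-hap": model.chrom_length,
        "M-hap": model.sdr_start + model.m_sdr_length + (model.chrom_length - model.sdr_end),
    }
    sdr_spans = {
        "f-hap": (model.sdr_start, model.sdr_end),
        "M-hap": (model.sdr_start, model.sdr_start + model.m_sdr_length),
    }

    tracks: dict[tuple[str, str], WindowDepthTrack] = {}
    for pool in POOLS:
        for assembly in ASSEMBLIES:
            starts, ends = _window_grid(lengths[assembly], window)
            lo, hi = sdr_spans[assembly]
            overlap = np.clip(np.minimum(ends, hi) - np.maximum(starts, lo), 0, None)
            frac_sdr = overlap / (ends - starts)
            units = frac_sdr * sdr_units[(pool, assembly)] + (1 - frac_sdr) * flank_units
            raw = rng.poisson(unit_coverage * units).astype(float)
            flank_mask = overlap == 0
            tracks[(pool, assembly)] = WindowDepthTrack(
                assembly=assembly,
                pool=pool,
                window=window,
                starts=starts,
                ends=ends,
                raw=raw,
                flank_mask=flank_mask,
            )
    return tracks


def simulate_ase_counts(
    model: SDRModel,
    panel: GenotypePanel,
    effect_spec: Mapping[str, Mapping[str, float]] | None = None,
    mean_depth: float = 30.0,
    base_error: float = 0.005,
    seed: int = 0,
) -> AseCountTable:
    """Simulate allele-specific expression counts for a sample panel.

    Wraps the RNA depth simulator and restricts the output to sex-linked
    sites inside annotated genes: only transcribed positions are covered,
    and the H1/H2-diagnostic markers of region B represent structural
    (untranscribed) divergence rather than exonic SNPs, so they carry no
    expression signal.  The sample phenotype factors (female-sterile /
    male-sterile) are attached for the association test.
    """
    if "phenotype" not in panel.accessions:
        raise ValueError("panel accessions lack phenotype labels")
    spec = DEFAULT_EFFECT_SPEC if effect_spec is None else effect_spec
    table = simulate_allele_depths(
        panel,
        mean_depth=mean_depth,
        base_error=base_error,
        seed=seed,
        source="RNA",
        model=model,
        effect_spec=spec,
    )
    genes = model.gene_of(table.positions)
    sex_linked = panel.sites["sex_linked"].to_numpy()
    keep = (genes != "") & sex_linked
    pheno = panel.accessions["phenotype"].to_numpy()
    factors = pd.DataFrame(
        {
            "sample": panel.accessions["id"],
            "female_sterile": pheno == "male",
            "male_sterile": pheno == "female",
        }
    )
    return AseCountTable(
        samples=table.samples,
        positions=table.positions[keep],
        genes=genes[keep].astype(str),
        ref=table.ref[:, keep],
        alt=table.alt[:, keep],
        factors=factors,
    )


def simulate_inp1_read_lengths(
    panel: GenotypePanel,
    depth: int = 30,
    base_error: float = 0.005,
    seed: int = 0,
) -> list[np.ndarray]:
    """Simulate lengths of reads spanning the VviINP1 8 bp indel.

    Each read samples one of the accession's two haplotypes uniformly and
    reports the corresponding amplicon length (intact, or 8 bp shorter on
    the f haplotype); with probability ``base_error`` the measured length
    is off by one.  Returns one array of read lengths per accession.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    _check_rate("base_error", base_error, upper=0.5)
    rng = np.random.default_rng(seed)
    intact = len(INP1_INTACT_SEQ)
    deleted = len(INP1_DELETED_SEQ)
    out = []
    for _, acc in panel.accessions.iterrows():
        allele_lengths = np.array(
            [deleted if h == "f" else intact for h in (acc["hap_a"], acc["hap_b"])]
        )
        lengths = allele_lengths[rng.integers(0, 2, size=depth)].astype(int)
        jitter = rng.random(depth) < base_error
        lengths[jitter] += rng.choice([-1, 1], size=int(jitter.sum()))
        out.append(lengths)
    return out
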