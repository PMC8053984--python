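"""Canonical model of the grapevine sex-determining region (SDR).

Wild grapevines (*Vitis* spp.) are dioecious: females are f/f and males are
M/f at a single ~145.5 kb region on chromosome 2, with genetic dominance
M > H > f.  Cultivated hermaphrodites carry one of two recombinant
haplotypes, H1 (a single crossover) or H2 (a double crossover), both
chimeras of the M and f haplotypes.  The three crossover breakpoints
partition the SDR into four gene regions:

``A``
    female-sterility region (*VviYABBY3*, *VviSKU5*); f-like on every
    hermaphrodite haplotype.
``B``
    breakpoint region (beta-fructofuranosidase, transaldolase); harbours
    no sex-linked SNPs, only markers that separate H1 from H2.
``C``
    male-sterility region (11 genes including *VviINP1*, which carries an
    8 bp frameshift deletion on the f haplotype); M-like on every
    hermaphrodite haplotype.
``D``
    distal region (*VviAPT3*); M-like on H1 but f-like on H2, which is why
    *VviAPT3* can be excluded as the female-sterility gene.

This module builds the coordinate model (breakpoints, regions, genes,
sex-linked sites), exposes the four haplotype templates, and defines the
genotype-class algebra (10 unordered diploid combinations and their
per-region numeric signatures) shared by the painter and the predictor.

Coordinates are 0-based half-open throughout; VCF output is 1-based.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HAPLOTYPES = ("f", "M", "H1", "H2")
REGIONS = ("A", "B", "C", "D")
PHENOTYPES = ("female", "male", "hermaphrodite")

#: Per-haplotype indicator of M ancestry in regions A..D.  f is f-like
#: everywhere, M is M-like everywhere; H1 switches to M at the B/C
#: boundary, H2 is M-like only between the A/B and C/D boundaries.
REGION_M_ANCESTRY: Mapping[str, tuple[int, int, int, int]] = {
    "f": (0, 0, 0, 0),
    "M": (1, 1, 1, 1),
    "H1": (0, 0, 1, 1),
    "H2": (0, 1, 1, 0),
}

_CANONICAL_ORDER = {"H1": 0, "H2": 1, "M": 2, "f": 3}

# VviINP1 8 bp indel marker.  The f haplotype lacks an 8 bp segment that
# is present on M, H1 and H2; its loss causes a frameshift and premature
# stop, the male-sterility mutation.  The sequences below are synthetic
# stand-ins for the amplicon around the indel (motif plus flanks), sized
# so that the intact and deleted alleles differ by exactly 8 bp.
INP1_MOTIF = "TTCCGGCA"
_INP1_FLANK5 = "ATGGCTTCAGGTACTGAACCGTTA"
_INP1_FLANK3 = "GGACCTTACGAGTTCAACTTGATC"
INP1_INTACT_SEQ = _INP1_FLANK5 + INP1_MOTIF + _INP1_FLANK3
INP1_DELETED_SEQ = _INP1_FLANK5 + _INP1_FLANK3


def _check_haplotype(hap: str) -> None:
    if hap not in HAPLOTYPES:
        raise ValueError(f"unknown haplotype {hap!r}; expected one of {HAPLOTYPES}")


def class_name(hap_a: str, hap_b: str) -> str:
    """Canonical label for an unordered haplotype pair, e.g. ``'H1/f'``."""
    _check_haplotype(hap_a)
    _check_haplotype(hap_b)
    a, b = sorted((hap_a, hap_b), key=_CANONICAL_ORDER.__getitem__)
    return f"{a}/{b}"


def class_haplotypes(label: str) -> tuple[str, str]:
    """Inverse of :func:`class_name`."""
    a, _, b = label.partition("/")
    _check_haplotype(a)
    _check_haplotype(b)
    return a, b


#: The 10 unordered diploid combinations of {f, M, H1, H2}.
CLASSES: tuple[str, ...] = tuple(
    sorted(
        {class_name(a, b) for a, b in itertools.combinations_with_replacement(HAPLOTYPES, 2)},
        key=lambda lab: tuple(_CANONICAL_ORDER[h] for h in class_haplotypes(lab)),
    )
)


def class_signature(label: str) -> tuple[int, int, int, int]:
    """Per-region numeric genotype (count of M-like alleles in A..D).

    0 = homozygous f-allele, 1 = heterozygous, 2 = homozygous M-allele.
    """
    a, b = class_haplotypes(label)
    return tuple(x + y for x, y in zip(REGION_M_ANCESTRY[a], REGION_M_ANCESTRY[b]))


#: Signature table for all 10 classes; a bijection (each 4-vector is unique).
SIGNATURES: Mapping[str, tuple[int, int, int, int]] = {
    lab: class_signature(lab) for lab in CLASSES
}


def phenotype_of(hap_a: str, hap_b: str) -> str:
    """Flower sex phenotype of a haplotype pair under dominance M > H > f."""
    _check_haplotype(hap_a)
    _check_haplotype(hap_b)
    pair = (hap_a, hap_b)
    if "M" in pair:
        return "male"
    if any(h.startswith("H") for h in pair):
        return "hermaphrodite"
    return "female"


def phenotype_of_class(label: str) -> str:
    return phenotype_of(*class_haplotypes(label))


def sterility_factors(label: str) -> tuple[bool, bool]:
    """Two-factor decomposition of flower sex: (female_sterile, male_sterile).

    Female-sterile iff at least one haplotype is M-like in region A (the
    female-sterility region); male-sterile iff neither haplotype is M-like
    in region C (no functional *VviINP1*).  Equivalent to the dominance
    rule: male = female-sterile only, female = male-sterile only,
    hermaphrodite = neither.
    """
    a, b = class_haplotypes(label)
    n_m_a = REGION_M_ANCESTRY[a][0] + REGION_M_ANCESTRY[b][0]
    n_m_c = REGION_M_ANCESTRY[a][2] + REGION_M_ANCESTRY[b][2]
    return n_m_a >= 1, n_m_c == 0


def inp1_allele_of(hap: str) -> str:
    """INP1 indel state carried by a haplotype: f is deleted, M/H intact."""
    _check_haplotype(hap)
    return "deleted" if hap == "f" else "intact"


@dataclass(frozen=True)
class HaplotypeTemplate:
    """One of the four SDR haplotypes expressed over the model's sites.

    ``alleles[i]`` is 1 where the haplotype carries the M-allele at site i
    and 0 where it carries the f-allele; ``ancestry[i]`` is the underlying
    chromosomal ancestry ('f' or 'M') at the site's position.
    """

    name: str
    alleles: np.ndarray
    ancestry: np.ndarray
    inp1_allele: str


DEFAULT_CONFIG: Mapping[str, object] = {
    "chrom": "chr2_f",
    "sdr_start": 50_000,
    # region lengths sum to the 145.5 kb f-haplotype SDR span
    "len_a": 20_000,
    "len_b": 8_000,
    "len_c": 60_000,
    "len_d": 57_500,
    "flank": 50_000,
    # sex-linked site counts (A + C + D = 1,066; none in B)
    "n_sites_a": 200,
    "n_sites_c": 500,
    "n_sites_d": 366,
    "n_b_diagnostic": 50,
    "site_seed": 2021,
    "m_sdr_length": 226_100,
    "apt3_offset": 47_000,
    "apt3_length": 2_500,
}


@dataclass(frozen=True, eq=False)
class SDRModel:
    """Coordinates, genes, sites and haplotype templates of the SDR.

    ``sites`` has columns ``pos`` (0-based), ``region`` (A..D),
    ``sex_linked`` (bool) and ``kind`` ('sex_linked' or 'b_diagnostic').
    ``gene_map`` has columns ``name``, ``start``, ``end``, ``strand``,
    ``region``.
    """

    chrom: str
    chrom_length: int
    sdr_start: int
    sdr_end: int
    b_ab: int
    b_bc: int
    b_cd: int
    sites: pd.DataFrame
    gene_map: pd.DataFrame
    m_sdr_length: int
    site_seed: int

    # -- coordinate helpers -------------------------------------------------

    @property
    def flank_left(self) -> tuple[int, int]:
        return (0, self.sdr_start)

    @property
    def flank_right(self) -> tuple[int, int]:
        return (self.sdr_end, self.chrom_length)

    @property
    def region_bounds(self) -> Mapping[str, tuple[int, int]]:
        return {
            "A": (self.sdr_start, self.b_ab),
            "B": (self.b_ab, self.b_bc),
            "C": (self.b_bc, self.b_cd),
            "D": (self.b_cd, self.sdr_end),
        }

    @property
    def positions(self) -> np.ndarray:
        return self.sites["pos"].to_numpy()

    def region_of(self, positions: Iterable[int]) -> np.ndarray:
        """Region label (A..D) per position, '' outside the SDR."""
        pos = np.asarray(list(positions) if not isinstance(positions, np.ndarray) else positions)
        edges = np.array([self.sdr_start, self.b_ab, self.b_bc, self.b_cd, self.sdr_end])
        idx = np.searchsorted(edges, pos, side="right") - 1
        labels = np.array(["", "A", "B", "C", "D", ""], dtype="<U1")
        return labels[np.clip(idx, -1, 4) + 1]

    def gene_of(self, positions: Iterable[int]) -> np.ndarray:
        """Name of the gene containing each position, or '' if intergenic."""
        pos = np.asarray(positions)
        out = np.full(pos.shape, "", dtype=object)
        for _, g in self.gene_map.iterrows():
            out[(pos >= g["start"]) & (pos < g["end"])] = g["name"]
        return out

    # -- haplotype templates ------------------------------------------------

    def ancestry_of(self, hap: str, positions: Iterable[int]) -> np.ndarray:
        """Chromosomal ancestry ('f' or 'M') of a haplotype at positions."""
        _check_haplotype(hap)
        pos = np.asarray(positions)
        if hap == "f":
            return np.full(pos.shape, "f", dtype="<U1")
        if hap == "M":
            return np.full(pos.shape, "M", dtype="<U1")
        if hap == "H1":
            return np.where(pos < self.b_bc, "f", "M").astype("<U1")
        # H2: double crossover, M-like only on [b_ab, b_cd)
        return np.where((pos >= self.b_ab) & (pos < self.b_cd), "M", "f").astype("<U1")

    def template(self, hap: str) -> HaplotypeTemplate:
        ancestry = self.ancestry_of(hap, self.positions)
        alleles = (ancestry == "M").astype(np.uint8)
        return HaplotypeTemplate(
            name=hap, alleles=alleles, ancestry=ancestry, inp1_allele=inp1_allele_of(hap)
        )

    def compose_genotype(self, hap_a: str, hap_b: str) -> np.ndarray:
        """Diploid dosage of M-alleles (0/1/2) per site for a haplotype pair."""
        return (self.template(hap_a).alleles + self.template(hap_b).alleles).astype(np.int8)

    def region_call_mask(self, region: str) -> np.ndarray:
        """Boolean mask over sites used to call the region's numeric state.

        Regions A, C, D use their sex-linked sites; region B, which has
        none, uses the H1-vs-H2 diagnostic markers placed there.
        """
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        in_region = (self.sites["region"] == region).to_numpy()
        if region == "B":
            return in_region & (self.sites["kind"] == "b_diagnostic").to_numpy()
        return in_region & self.sites["sex_linked"].to_numpy()

    @property
    def n_sex_linked(self) -> int:
        return int(self.sites["sex_linked"].sum())


def _default_gene_map(sdr_start: int, b_ab: int, b_bc: int, b_cd: int,
                      apt3_offset: int, apt3_length: int) -> pd.DataFrame:
    rows = [
        # region A: female-sterility candidates
        ("VviYABBY3", sdr_start + 2_000, sdr_start + 6_000, "+", "A"),
        ("VviSKU5", sdr_start + 10_000, sdr_start + 14_500, "+", "A"),
        # region B: the breakpoint region.  Transaldolase is on the minus
        # strand so its 5' end abuts the B/C boundary (the H1 crossover)
        # and its 3'-end intron lies near the A/B boundary (the first H2
        # crossover).
        ("beta-fructofuranosidase", b_ab + 500, b_ab + 2_500, "+", "B"),
        ("transaldolase", b_ab + 3_000, b_bc - 200, "-", "B"),
    ]
    # region C: 11 genes including the male-sterility candidate VviINP1
    c_names = [
        "VviTPP", "VviINP1", "VviKASIII", "VviPLATZ", "VviWRKY",
        "VviC06", "VviC07", "VviC08", "VviC09", "VviC10", "VviC11",
    ]
    for i, name in enumerate(c_names):
        start = b_bc + 1_500 + i * 5_200
        rows.append((name, start, start + 3_000, "+" if i % 2 == 0 else "-", "C"))
    # region D: VviAPT3, 47 kb downstream of the C/D breakpoint
    rows.append(("VviAPT3", b_cd + apt3_offset, b_cd + apt3_offset + apt3_length, "+", "D"))
    return pd.DataFrame(rows, columns=["name", "start", "end", "strand", "region"])


def _draw_sites(rng: np.random.Generator, lo: int, hi: int, n: int) -> np.ndarray:
    if n > hi - lo:
        raise ValueError(f"cannot place {n} sites in [{lo}, {hi})")
    return np.sort(rng.choice(np.arange(lo, hi), size=n, replace=False))


def build_sdr_model(config: Mapping[str, object] | None = None) -> SDRModel:
    """Construct the SDR model from a flat configuration mapping.

    Unspecified keys fall back to :data:`DEFAULT_CONFIG`, which encodes the
    145.5 kb f-haplotype span, the A/B/C/D region structure, the default
    gene map, and 1,066 sex-linked sites (none in region B) placed
    uniformly at random within their regions under a fixed seed.

    Explicit site positions may be supplied via ``site_positions``, a
    mapping from region label to an iterable of positions (region B
    entries become H1/H2-diagnostic markers).
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})

    sdr_start = int(cfg["sdr_start"])
    lens = {k: int(cfg[f"len_{k.lower()}"]) for k in REGIONS}
    if sdr_start <= 0:
        raise ValueError("sdr_start must be positive (the left flank precedes it)")
    if any(v <= 0 for v in lens.values()):
        raise ValueError(f"region lengths must be positive, got {lens}")

    b_ab = sdr_start + lens["A"]
    b_bc = b_ab + lens["B"]
    b_cd = b_bc + lens["C"]
    sdr_end = b_cd + lens["D"]
    if not (sdr_start < b_ab < b_bc < b_cd < sdr_end):
        raise ValueError("breakpoints must satisfy sdr_start < b_AB < b_BC < b_CD < sdr_end")

    flank = int(cfg["flank"])
    if flank < sdr_start:
        # left flank is [0, sdr_start); keep the right flank the same width
        pass
    chrom_length = sdr_end + flank

    apt3_offset = int(cfg["apt3_offset"])
    apt3_length = int(cfg["apt3_length"])
    if b_cd + apt3_offset + apt3_length > sdr_end:
        raise ValueError("VviAPT3 interval does not fit inside region D")

    gene_map = _default_gene_map(sdr_start, b_ab, b_bc, b_cd, apt3_offset, apt3_length)
    bounds = {
        "A": (sdr_start, b_ab),
        "B": (b_ab, b_bc),
        "C": (b_bc, b_cd),
        "D": (b_cd, sdr_end),
    }
    for _, g in gene_map.iterrows():
        lo, hi = bounds[g["region"]]
        if not (lo <= g["start"] < g["end"] <= hi):
            raise ValueError(
                f"gene {g['name']} [{g['start']}, {g['end']}) crosses the "
                f"boundary of region {g['region']} [{lo}, {hi})"
            )

    site_seed = int(cfg["site_seed"])
    explicit = cfg.get("site_positions")
    per_region: dict[str, np.ndarray] = {}
    if explicit is not None:
        for region in REGIONS:
            pos = np.sort(np.asarray(list(explicit.get(region, ())), dtype=int))
            lo, hi = bounds[region]
            if pos.size and (pos.min() < lo or pos.max() >= hi):
                raise ValueError(f"explicit site outside region {region} bounds")
            per_region[region] = pos
    else:
        rng = np.random.default_rng(site_seed)
        per_region["A"] = _draw_sites(rng, *bounds["A"], int(cfg["n_sites_a"]))
        per_region["B"] = _draw_sites(rng, *bounds["B"], int(cfg["n_b_diagnostic"]))
        per_region["C"] = _draw_sites(rng, *bounds["C"], int(cfg["n_sites_c"]))
        per_region["D"] = _draw_sites(rng, *bounds["D"], int(cfg["n_sites_d"]))

    frames = []
    for region in REGIONS:
        pos = per_region.get(region, np.array([], dtype=int))
        kind = "b_diagnostic" if region == "B" else "sex_linked"
        frames.append(
            pd.DataFrame(
                {
                    "pos": pos,
                    "region": region,
                    "sex_linked": region != "B",
                    "kind": kind,
                }
            )
        )
    sites = pd.concat(frames, ignore_index=True).sort_values("pos", ignore_index=True)

    return SDRModel(
        chrom=str(cfg["chrom"]),
        chrom_length=chrom_length,
        sdr_start=sdr_start,
        sdr_end=sdr_end,
        b_ab=b_ab,
        b_bc=b_bc,
        b_cd=b_cd,
        sites=sites,
        gene_map=gene_map,
        m_sdr_length=int(cfg["m_sdr_length"]),
        site_seed=site_seed,
    )
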