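"""Chromosome painting, breakpoint detection, and genotype classification.

Painting renders each accession's genotype at the model's sites as a
0/1/2 state relative to the f allele (homozygous f / heterozygous /
homozygous M) - the allelic-state heat map that exposes the recombinant
structure of the hermaphrodite haplotypes.  Region-wise modal states give
a numeric genotype 4-vector which identifies one of the 10 diploid
haplotype combinations; transitions in a single haplotype's ancestry
locate the recombination breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import REGIONS, SDRModel, SIGNATURES

MISSING = -1


@dataclass(eq=False)
class PaintedAccession:
    """Per-site allelic states of one accession, with run segments.

    ``states`` are 0/1/2 (-1 missing) aligned to ``positions``;
    ``segments`` are (start_pos, end_pos, state) maximal runs of equal
    non-missing state, and ``breakpoints`` the midpoints between
    consecutive segments.
    """

    positions: np.ndarray
    states: np.ndarray
    segments: list[tuple[int, int, int]]
    breakpoints: list[int]


@dataclass(frozen=True)
class NumericGenotype:
    """Per-region numeric state with its supporting evidence.

    ``values`` holds one entry per region A..D: 0 (homozygous f), 1
    (heterozygous), 2 (homozygous M) or None (no-call); ``support`` the
    number of informative sites and ``concordance`` the modal-state
    frequency among them.
    """

    values: tuple[int | None, int | None, int | None, int | None]
    support: tuple[int, int, int, int]
    concordance: tuple[float, float, float, float]


def _state_runs(positions: np.ndarray, states: np.ndarray):
    """Maximal runs of equal non-missing state and their midpoints."""
    informative = states >= 0
    pos = positions[informative]
    st = states[informative]
    segments: list[tuple[int, int, int]] = []
    breakpoints: list[int] = []
    if pos.size == 0:
        return segments, breakpoints
    start = pos[0]
    prev_pos = pos[0]
    prev_state = st[0]
    for p, s in zip(pos[1:], st[1:]):
        if s != prev_state:
            segments.append((int(start), int(prev_pos), int(prev_state)))
            # midpoint between flanking informative sites; floor division
            # breaks ties toward the lower coordinate
            breakpoints.append(int((prev_pos + p) // 2))
            start = p
        prev_pos = p
        prev_state = s
    segments.append((int(start), int(prev_pos), int(prev_state)))
    return segments, breakpoints


def paint_sites(
    genotypes: Iterable[int],
    positions: Iterable[int],
    model: SDRModel,
) -> PaintedAccession:
    """Paint one accession's genotypes onto the model's site grid.

    ``genotypes`` are M-allele dosages (0/1/2, -1 missing) at
    ``positions``; positions absent from the model are dropped, model
    sites absent from the input are painted missing.
    """
    g = np.asarray(list(genotypes) if not isinstance(genotypes, np.ndarray) else genotypes)
    pos = np.asarray(list(positions) if not isinstance(positions, np.ndarray) else positions)
    if g.shape != pos.shape:
        raise ValueError("genotypes and positions must have equal length")
    model_pos = model.positions
    idx = {int(p): i for i, p in enumerate(model_pos)}
    states = np.full(model_pos.size, MISSING, dtype=np.int8)
    n_overlap = 0
    for p, gt in zip(pos, g):
        i = idx.get(int(p))
        if i is not None:
            states[i] = gt
            n_overlap += 1
    if n_overlap == 0:
        raise ValueError("no overlap between genotyped sites and model sites")
    segments, breakpoints = _state_runs(model_pos, states)
    return PaintedAccession(
        positions=model_pos.copy(), states=states, segments=segments, breakpoints=breakpoints
    )


def region_numeric(
    painted: PaintedAccession,
    model: SDRModel,
    min_sites: int = 5,
    min_concordance: float = 0.8,
) -> NumericGenotype:
    """Collapse painted states into a per-region numeric genotype.

    Per region the modal non-missing state is called when it is supported
    by at least ``min_sites`` sites and reaches frequency
    ``min_concordance`` among them; otherwise the region is a no-call.
    Regions A, C and D are called from their sex-linked sites; region B
    from the H1/H2-diagnostic markers.
    """
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    if not (0.5 < min_concordance <= 1.0):
        raise ValueError("min_concordance must lie in (0.5, 1]")
    values = []
    support = []
    concordance = []
    for region in REGIONS:
        mask = model.region_call_mask(region)
        states = painted.states[mask]
        states = states[states >= 0]
        n = states.size
        if n == 0:
            values.append(None)
            support.append(0)
            concordance.append(float("nan"))
            continue
        counts = np.bincount(states, minlength=3)
        modal = int(counts.argmax())
        conc = counts[modal] / n
        values.append(modal if (n >= min_sites and conc >= min_concordance) else None)
        support.append(n)
        concordance.append(float(conc))
    return NumericGenotype(
        values=tuple(values), support=tuple(support), concordance=tuple(concordance)
    )


def classify_genotype(numeric: NumericGenotype | Sequence[int | None]) -> str:
    """Map a numeric genotype 4-vector onto one of the 10 classes.

    A fully called vector must match a signature exactly.  With one
    no-call region the unique signature consistent with the called
    regions is returned when it exists; contradictory or ambiguous
    vectors return 'unknown'.  Fewer than 3 called regions is an error.
    """
    values = numeric.values if isinstance(numeric, NumericGenotype) else tuple(numeric)
    if len(values) != 4:
        raise ValueError("numeric genotype must have 4 region entries")
    called = [v is not None for v in values]
    if sum(called) < 3:
        raise ValueError("classification requires at least 3 called regions")
    matches = [
        label
        for label, sig in SIGNATURES.items()
        if all(v is None or v == s for v, s in zip(values, sig))
    ]
    return matches[0] if len(matches) == 1 else "unknown"


def detect_breakpoints(
    ancestry: Iterable[str],
    positions: Iterable[int],
) -> list[int]:
    """Recombination breakpoints of a single haplotype's ancestry vector.

    ``ancestry`` holds 'f' or 'M' per site (anything else is treated as
    missing).  A breakpoint is placed at each transition between maximal
    same-ancestry runs, at the floor midpoint of the flanking informative
    sites.
    """
    anc = np.asarray(list(ancestry))
    pos = np.asarray(list(positions) if not isinstance(positions, np.ndarray) else positions)
    if anc.shape != pos.shape:
        raise ValueError("ancestry and positions must have equal length")
    codes = np.where(anc == "f", 0, np.where(anc == "M", 1, MISSING)).astype(np.int8)
    if not (codes >= 0).any():
        raise ValueError("ancestry vector has no informative sites")
    _, breakpoints = _state_runs(pos, codes)
    return breakpoints


def template_breakpoints(model: SDRModel, hap: str) -> list[int]:
    """Breakpoints recovered from a haplotype template's own ancestry."""
    tmpl = model.template(hap)
    return detect_breakpoints(tmpl.ancestry, model.positions)
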