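"""Readers and writers for the standard interchange formats.

Genotype panels travel as VCF v4.2 (GT, optionally AD), allele depths as
flat TSV (sample, chrom, pos, ref_count, alt_count), model regions and
genes as BED6, depth tracks as bedGraph, and configurations as flat
key=value files.  Reading VCF goes through cyvcf2; positions are 1-based
in files and 0-based in memory.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import SDRModel
from .simulate import AlleleDepthTable, GenotypePanel, WindowDepthTrack

_BASES = "ACGT"


def _site_alleles(pos: int) -> tuple[str, str]:
    """Deterministic synthetic ref/alt bases for a simulated site."""
    ref_i = pos % 4
    alt_i = (ref_i + 1 + (pos // 7) % 3) % 4
    return _BASES[ref_i], _BASES[alt_i]


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(
    panel: GenotypePanel,
    path: str | os.PathLike,
    depths: AlleleDepthTable | None = None,
    chrom_length: int | None = None,
) -> None:
    """Write a genotype panel as VCF v4.2 (GT field, missing './.').

    When an allele-depth table over the same samples and sites is given,
    per-genotype AD fields are emitted as well.  INFO carries the site
    annotation (REGION, KIND).
    """
    chrom = panel.meta.get("chrom", "chr2_f")
    samples = list(panel.accessions["id"])
    if depths is not None:
        if depths.samples != samples or not np.array_equal(depths.positions, panel.positions):
            raise ValueError("depth table does not match the panel's samples/sites")
    lines = [
        "##fileformat=VCFv4.2",
        "##source=vitis-sdr",
        f"##contig=<ID={chrom}"
        + (f",length={chrom_length}>" if chrom_length else ">"),
        '##INFO=<ID=REGION,Number=1,Type=String,Description="SDR region (A-D) or flank">',
        '##INFO=<ID=KIND,Number=1,Type=String,Description="sex_linked, b_diagnostic or neutral">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    fmt = "GT"
    if depths is not None:
        lines.append(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">'
        )
        fmt = "GT:AD"
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))

    for j, site in panel.sites.iterrows():
        pos0 = int(site["pos"])
        ref, alt = _site_alleles(pos0)
        info = f"REGION={site['region']};KIND={site['kind']}"
        fields = []
        for i in range(panel.n_accessions):
            gt = _GT_STRINGS[int(panel.genotypes[i, j])]
            if depths is not None:
                gt += f":{depths.ref[i, j]},{depths.alt[i, j]}"
            fields.append(gt)
        lines.append(
            f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\t{fmt}\t" + "\t".join(fields)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str | os.PathLike):
    """Read a VCF into (positions, genotypes, samples, allele_depths).

    Positions are 0-based; genotypes are M-allele dosages with -1 for
    missing; ``allele_depths`` is an (n_samples, n_sites, 2) array or
    None when the file lacks AD.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    positions, gts, ads = [], [], []
    has_ad = False
    for variant in vcf:
        positions.append(variant.POS - 1)
        g = variant.gt_types.copy()
        g[g == 3] = -1
        gts.append(g)
        try:
            ad = variant.format("AD")
        except KeyError:  # cyvcf2 raises when AD is absent from the header
            ad = None
        if ad is not None:
            has_ad = True
            ads.append(ad[:, :2])
    vcf.close()
    positions = np.asarray(positions, dtype=int)
    genotypes = np.asarray(gts, dtype=np.int8).T  # (samples, sites)
    allele_depths = None
    if has_ad:
        allele_depths = np.stack(ads, axis=1)  # (samples, sites, 2)
        allele_depths = np.clip(allele_depths, 0, None)
    return positions, genotypes, samples, allele_depths


def write_depth_tsv(table: AlleleDepthTable, path: str | os.PathLike, chrom: str = "chr2_f") -> None:
    """Write an allele-depth table as long-format TSV (1-based positions)."""
    n_samples, n_sites = table.ref.shape
    df = pd.DataFrame(
        {
            "sample": np.repeat(table.samples, n_sites),
            "chrom": chrom,
            "pos": np.tile(table.positions + 1, n_samples),
            "ref_count": table.ref.ravel(),
            "alt_count": table.alt.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_depth_tsv(path: str | os.PathLike, source: str = "DNA") -> AlleleDepthTable:
    """Read a long-format allele-depth TSV back into a table."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "pos", "ref_count", "alt_count"}
    if not required.issubset(df.columns):
        raise ValueError(f"depth TSV must have columns {sorted(required)}")
    samples = list(dict.fromkeys(df["sample"]))
    positions = np.sort(df["pos"].unique()) - 1
    pos_idx = {p: i for i, p in enumerate(positions + 1)}
    samp_idx = {s: i for i, s in enumerate(samples)}
    ref = np.zeros((len(samples), positions.size), dtype=np.int64)
    alt = np.zeros_like(ref)
    ref[df["sample"].map(samp_idx), df["pos"].map(pos_idx)] = df["ref_count"]
    alt[df["sample"].map(samp_idx), df["pos"].map(pos_idx)] = df["alt_count"]
    return AlleleDepthTable(samples=samples, positions=positions, ref=ref, alt=alt, source=source)


def write_regions_bed(model: SDRModel, path: str | os.PathLike) -> None:
    """Write the A-D region intervals as BED6."""
    with open(path, "w") as fh:
        for region, (lo, hi) in model.region_bounds.items():
            fh.write(f"{model.chrom}\t{lo}\t{hi}\t{region}\t0\t+\n")


def write_genes_bed(model: SDRModel, path: str | os.PathLike) -> None:
    """Write the gene map as BED6 (name = gene, score = 0)."""
    with open(path, "w") as fh:
        for _, g in model.gene_map.iterrows():
            fh.write(
                f"{model.chrom}\t{g['start']}\t{g['end']}\t{g['name']}\t0\t{g['strand']}\n"
            )


def write_bedgraph(
    track: WindowDepthTrack, path: str | os.PathLike, which: str = "raw"
) -> None:
    """Write one depth track as bedGraph (chrom = '<assembly>')."""
    values = track.raw if which == "raw" else track.normalized
    if values is None:
        raise ValueError(f"track has no {which} values")
    with open(path, "w") as fh:
        for s, e, v in zip(track.starts, track.ends, values):
            fh.write(f"{track.assembly}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )


def write_sample_table(panel: GenotypePanel, path: str | os.PathLike) -> None:
    """Write per-accession labels (id, class, phenotype, sex) as TSV.

    ``sex`` is 'female'/'male' for dioecious accessions and 'NA' for
    hermaphrodites, matching the cosegregation scan's input convention.
    """
    df = panel.accessions[["id", "class_label", "phenotype"]].copy()
    sex = panel.sex_labels()
    df["sex"] = np.where(sex == "", "NA", sex)
    df.to_csv(path, sep="\t", index=False)


def read_sex_labels(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample-sex TSV; requires 'id' plus 'sex' or 'phenotype'.

    The literal string 'NA' marks non-dioecious accessions and is kept
    as-is rather than parsed as missing.
    """
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    if "id" not in df.columns or not ({"sex", "phenotype"} & set(df.columns)):
        raise ValueError("sample table needs an 'id' and a 'sex' or 'phenotype' column")
    return df


def load_config(path: str | os.PathLike) -> dict:
    """Parse a flat key=value configuration file.

    Blank lines and '#' comments are ignored; values are coerced to int,
    then float, then left as strings.
    """
    cfg: dict = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw.rstrip()}")
            key, _, value = line.partition("=")
            value = value.strip()
            for cast in (int, float):
                try:
                    value = cast(value)
                    break
                except ValueError:
                    continue
            cfg[key.strip()] = value
    return cfg
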