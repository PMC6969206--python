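"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA (one file per site) for haplotype alignments, a GenAlEx-style CSV for
diploid microsatellite genotypes (two columns per locus, a leading comment
line carrying the repeat-unit lengths), a site-metadata CSV, and square /
edge-list CSVs for matrices.
"""

from __future__ import annotations

import pathlib
from itertools import combinations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .popgen import DiffMatrix, GenotypeTable, HaplotypeSet

MISSING = 0


def write_fasta(hs: HaplotypeSet, path) -> None:
    records = []
    for k, seq in enumerate(hs.sequences):
        lineage = hs.lineages[k] if hs.lineages else ""
        rid = f"{hs.site}_{k:03d}"
        records.append(
            SeqRecord(Seq(seq), id=rid, description=lineage)
        )
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path, site: str | None = None) -> HaplotypeSet:
    path = pathlib.Path(path)
    seqs, lineages = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs.append(str(rec.seq).upper())
        desc = rec.description.split(maxsplit=1)
        lineages.append(desc[1] if len(desc) > 1 else "")
    if site is None:
        site = path.stem
    lin = lineages if any(lineages) else None
    return HaplotypeSet(site=site, sequences=seqs, lineages=lin)


def write_fasta_dir(sets: dict[str, HaplotypeSet], out_dir) -> None:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for code, hs in sets.items():
        write_fasta(hs, out / f"{code}.fasta")


def read_fasta_dir(in_dir) -> dict[str, HaplotypeSet]:
    out = {}
    for path in sorted(pathlib.Path(in_dir).glob("*.fasta")):
        hs = read_fasta(path)
        out[hs.site] = hs
    return out


def write_genotypes(gt: GenotypeTable, path) -> None:
    """GenAlEx-like CSV: '#repeat_units' comment line, then individual, site
    and two columns per locus (0 = missing)."""
    path = pathlib.Path(path)
    cols = {"individual": [f"ind{k:04d}" for k in range(gt.n)], "site": gt.sites}
    for l, locus in enumerate(gt.loci):
        cols[f"{locus}.1"] = gt.alleles[:, l, 0]
        cols[f"{locus}.2"] = gt.alleles[:, l, 1]
    with open(path, "w") as fh:
        fh.write(
            "#repeat_units,"
            + ",".join(f"{n}={u}" for n, u in zip(gt.loci, gt.repeat_units))
            + "\n"
        )
        pd.DataFrame(cols).to_csv(fh, index=False)


def read_genotypes(path) -> GenotypeTable:
    path = pathlib.Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#repeat_units"):
            raise ValueError("genotype CSV must start with a #repeat_units line")
        units = dict(
            item.split("=") for item in header.split(",", 1)[1].split(",")
        )
        df = pd.read_csv(fh)
    loci = [c[:-2] for c in df.columns if c.endswith(".1")]
    alleles = np.stack(
        [df[[f"{l}.1", f"{l}.2"]].to_numpy(dtype=int) for l in loci], axis=1
    )
    return GenotypeTable(
        sites=df["site"].to_numpy(),
        loci=loci,
        alleles=alleles,
        repeat_units=np.array([int(units[l]) for l in loci]),
    )


def write_sites(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, index=False)


def read_sites(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_matrix(values: np.ndarray, ids, path) -> None:
    pd.DataFrame(values, index=ids, columns=ids).to_csv(path)


def read_matrix(path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(df.index)


def write_diff_matrix(dm: DiffMatrix, out_prefix) -> None:
    """Write a DiffMatrix as <prefix>_values.csv and <prefix>_padj.csv."""
    out_prefix = pathlib.Path(out_prefix)
    write_matrix(dm.values, dm.ids, out_prefix.with_name(out_prefix.name + "_values.csv"))
    if dm.p_adj is not None:
        write_matrix(dm.p_adj, dm.ids, out_prefix.with_name(out_prefix.name + "_padj.csv"))
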