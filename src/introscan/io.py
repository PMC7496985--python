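"""Readers and writers for the standard formats the pipeline touches.

VCF (GT-only, biallelic SNPs), delimited trait tables, BED-style interval
tables, Newick trees and a two-column sample-group table.  All genotype
input flows through :func:`read_vcf`, which encodes diploid GT calls as
alternate-allele dosages; phased and unphased genotypes are treated
identically and multiallelic records are skipped (with a count).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from skbio import TreeNode

from .model import MISSING, GenotypeMatrix, SampleInfo, Window

logger = logging.getLogger(__name__)

_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


@dataclass
class VcfReadStats:
    """Bookkeeping from a VCF read: records skipped as non-biallelic-SNP."""

    n_kept: int = 0
    n_skipped_multiallelic: int = 0
    n_skipped_non_snp: int = 0


def read_vcf(
    path: str,
    groups: dict[str, str],
    region: Window | None = None,
    on_unknown_sample: str = "error",
) -> tuple[GenotypeMatrix, VcfReadStats]:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path:
        VCF file (plain or bgzipped) with GT calls.
    groups:
        Mapping accession id -> group label; every retained sample must
        appear here.
    region:
        Optional 0-based half-open window; only sites inside are kept.
    on_unknown_sample:
        ``"error"`` (default) raises if a VCF sample is absent from
        ``groups``; ``"drop"`` silently drops such samples.

    Returns
    -------
    (GenotypeMatrix, VcfReadStats)
        Samples keep VCF header order; sites keep file order (must be
        sorted); multiallelic and non-SNP records are skipped and counted.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if on_unknown_sample not in ("error", "drop"):
        raise ValueError("on_unknown_sample must be 'error' or 'drop'")
    vcf = VCF(path)
    try:
        vcf_samples = list(vcf.samples)
        unknown = [s for s in vcf_samples if s not in groups]
        if unknown and on_unknown_sample == "error":
            raise KeyError(
                f"VCF samples absent from group table: {unknown[:5]}"
                + ("..." if len(unknown) > 5 else "")
            )
        keep = [i for i, s in enumerate(vcf_samples) if s in groups]
        if not keep:
            raise ValueError("no VCF sample appears in the group table")
        samples = [SampleInfo(vcf_samples[i], groups[vcf_samples[i]]) for i in keep]
        keep_arr = np.asarray(keep, dtype=np.intp)

        stats = VcfReadStats()
        chroms: list[str] = []
        poss: list[int] = []
        refs: list[str] = []
        alts: list[str] = []
        rows: list[np.ndarray] = []
        for var in vcf:
            if len(var.ALT) != 1:
                stats.n_skipped_multiallelic += 1
                continue
            if len(var.REF) != 1 or len(var.ALT[0]) != 1 or var.ALT[0] == "*":
                stats.n_skipped_non_snp += 1
                continue
            if region is not None and not (
                var.CHROM == region.chrom and region.contains_pos(var.POS)
            ):
                continue
            # genotypes: rows [allele1, allele2, phased]; -1 encodes missing
            g = np.asarray(var.genotype.array(), dtype=np.int16)[keep_arr, :2]
            dose = g.sum(axis=1)
            dose[(g < 0).any(axis=1)] = MISSING
            chroms.append(var.CHROM)
            poss.append(var.POS)
            refs.append(var.REF)
            alts.append(var.ALT[0])
            rows.append(dose.astype(np.int8))
            stats.n_kept += 1
    finally:
        vcf.close()

    if stats.n_skipped_multiallelic:
        logger.info(
            "%s: skipped %d multiallelic records", path, stats.n_skipped_multiallelic
        )
    calls = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(
        samples,
        np.asarray(chroms, dtype=object),
        np.asarray(poss, dtype=np.int64),
        np.asarray(refs, dtype=object),
        np.asarray(alts, dtype=object),
        calls,
    )
    return gm, stats


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCFv4.2 with a GT-only FORMAT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in gm.chromosomes():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j in range(gm.n_sites):
            gts = "\t".join(_DOSAGE_TO_GT[int(d)] for d in gm.calls[:, j])
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_groups_table(gm_or_samples, path: str) -> None:
    """Write a two-column ``sample<TAB>group`` table with header."""
    samples = (
        gm_or_samples.samples
        if isinstance(gm_or_samples, GenotypeMatrix)
        else list(gm_or_samples)
    )
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for s in samples:
            fh.write(f"{s.id}\t{s.group}\n")


def read_groups_table(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep=None, engine="python")
    cols = [c.lower() for c in df.columns]
    if cols[:2] != ["sample", "group"]:
        raise ValueError(f"{path}: expected header 'sample, group', got {list(df.columns)}")
    dup = df.iloc[:, 0][df.iloc[:, 0].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate sample ids: {sorted(set(dup))[:5]}")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


# -- trait tables -------------------------------------------------------------

TRAIT_COLUMNS = ["accession", "trait", "environment", "value"]


def read_trait_table(path: str) -> pd.DataFrame:
    """Read a long-format trait table (accession, trait, environment, value).

    Duplicate (accession, trait, environment) rows and non-numeric values
    are rejected with 1-based line numbers in the error message.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if [c.strip().lower() for c in df.columns] != TRAIT_COLUMNS:
        raise ValueError(
            f"{path}: expected header {TRAIT_COLUMNS}, got {list(df.columns)}"
        )
    df.columns = TRAIT_COLUMNS
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.index[values.isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:5]]  # +1 header, +1 1-based
        raise ValueError(f"{path}: non-numeric value at line(s) {lines}")
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: non-finite trait values present")
    key = df[["accession", "trait", "environment"]]
    dupmask = key.duplicated(keep=False)
    if dupmask.any():
        first = key.index[key.duplicated()][0]
        raise ValueError(
            f"{path}: duplicate (accession,trait,environment) at line {int(first) + 2}"
        )
    out = df.copy()
    out["value"] = values.astype(float)
    return out


def write_trait_table(tt: pd.DataFrame, path: str) -> None:
    tt.to_csv(path, index=False, float_format="%.6g")


# -- interval sets ------------------------------------------------------------

INTERVAL_COLUMNS = ["chrom", "start", "end", "label", "source"]


def intervals_frame(
    windows: list[Window], labels: list[str], source: str
) -> pd.DataFrame:
    """Build an interval-set frame (chrom, start, end, label, source)."""
    if len(windows) != len(labels):
        raise ValueError("windows and labels must have equal length")
    if len(set(labels)) != len(labels):
        raise ValueError(f"labels not unique within source {source!r}")
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "label": labels,
            "source": source,
        }
    )


def read_intervals(path: str) -> pd.DataFrame:
    """Read a delimited interval table with header chrom,start,end,label,source."""
    df = pd.read_csv(path, sep=None, engine="python")
    have = [c.strip().lower() for c in df.columns]
    if have[:3] != ["chrom", "start", "end"]:
        raise ValueError(f"{path}: expected at least columns chrom,start,end")
    df.columns = have
    if "label" not in df:
        df["label"] = [f"iv{i + 1}" for i in range(len(df))]
    if "source" not in df:
        df["source"] = os.path.basename(path)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])]
    if len(bad):
        raise ValueError(f"{path}: invalid interval at line {int(bad[0]) + 2}")
    return df[INTERVAL_COLUMNS]


def write_intervals_bed(ivs: pd.DataFrame, path: str) -> None:
    """Write intervals as BED3+ (0-based half-open), sorted by (chrom, start)."""
    cols = [c for c in ["chrom", "start", "end", "label", "source"] if c in ivs]
    out = ivs[cols].sort_values(["chrom", "start", "end"], kind="mergesort")
    out.to_csv(path, sep="\t", header=False, index=False)


def intervals_to_windows(ivs: pd.DataFrame) -> list[Window]:
    return [
        Window(str(r.chrom), int(r.start), int(r.end)) for r in ivs.itertuples()
    ]


# -- trees --------------------------------------------------------------------

def clamp_negative_branches(tree: TreeNode) -> TreeNode:
    """Return a copy with negative branch lengths clamped to zero."""
    t = tree.copy()
    for node in t.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return t


def write_newick(tree: TreeNode, path: str) -> None:
    """Write a tree as Newick with branch lengths (negatives clamped at 0)."""
    clamp_negative_branches(tree).write(path, format="newick")


def read_newick(path: str) -> TreeNode:
    return TreeNode.read(path, format="newick")
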