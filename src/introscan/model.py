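"""Shared in-memory data model.

The pipeline works on diploid biallelic SNP genotypes stored as
alternate-allele dosages (0, 1, 2) with :data:`MISSING` (-1) for uncalled
genotypes.  Coordinates follow two conventions that are kept strictly
separate:

* VCF positions are 1-based (as in the format itself);
* every :class:`Window` and every BED-style interval is 0-based half-open.

A VCF site at position ``p`` belongs to a window iff ``start <= p - 1 < end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Dosage code for an uncalled genotype.
MISSING: int = -1

#: Trait codes used throughout (lint percentage, seed cotton weight, lint
#: weight, fibre length, fibre strength, micronaire, fibre uniformity,
#: short fibre content, fibre elongation).
FIBRE_TRAITS: tuple[str, ...] = (
    "LP", "SCW", "LW", "FL", "FS", "MV", "FU", "SFC", "FE",
)


@dataclass(frozen=True)
class SampleInfo:
    """An accession with its population-group label (e.g. ``Gh``/``Gb``)."""

    id: str
    group: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sample id must be non-empty")
        if not self.group:
            raise ValueError(f"sample {self.id!r}: group must be non-empty")


@dataclass(frozen=True, order=True)
class Window:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid window {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos: int) -> bool:
        """Whether a 1-based VCF position falls inside this window."""
        return self.start <= pos - 1 < self.end

    def overlaps(self, other: "Window") -> bool:
        return self.chrom == other.chrom and (
            max(self.start, other.start) < min(self.end, other.end)
        )


class GenotypeMatrix:
    """Accessions x biallelic SNPs as diploid alternate-allele dosages.

    Parameters
    ----------
    samples:
        Ordered accessions; ids must be unique.
    chrom, pos, ref, alt:
        Per-site arrays.  ``pos`` is 1-based.  Sites must be grouped by
        chromosome with strictly increasing positions within each
        chromosome block.
    calls:
        ``(n_samples, n_sites)`` integer array of dosages in
        ``{0, 1, 2, MISSING}``.
    """

    def __init__(
        self,
        samples: Sequence[SampleInfo],
        chrom: np.ndarray,
        pos: np.ndarray,
        ref: np.ndarray,
        alt: np.ndarray,
        calls: np.ndarray,
    ) -> None:
        self.samples = list(samples)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = np.asarray(alt, dtype=object)
        self.calls = np.asarray(calls, dtype=np.int8)
        self.validate()

    # -- construction helpers -------------------------------------------------

    def validate(self) -> None:
        n_samples, n_sites = self.calls.shape
        if n_samples != len(self.samples):
            raise ValueError("calls row count does not match sample count")
        for arr, name in (
            (self.chrom, "chrom"), (self.pos, "pos"),
            (self.ref, "ref"), (self.alt, "alt"),
        ):
            if arr.shape != (n_sites,):
                raise ValueError(f"{name} length does not match site count")
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        bad = (self.calls < MISSING) | (self.calls > 2)
        if bad.any():
            raise ValueError("calls must be in {0,1,2,MISSING}")
        if np.any(self.pos < 1):
            raise ValueError("positions are 1-based; pos >= 1 required")
        # chromosome blocks contiguous, positions strictly increasing within
        seen: set[str] = set()
        prev_chrom: str | None = None
        for i in range(n_sites):
            c = self.chrom[i]
            if c != prev_chrom:
                if c in seen:
                    raise ValueError(f"sites for chromosome {c} not contiguous")
                seen.add(c)
                prev_chrom = c
            elif self.pos[i] <= self.pos[i - 1]:
                raise ValueError(
                    f"positions not strictly increasing on {c} at index {i}"
                )

    # -- basic accessors ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    @property
    def groups(self) -> list[str]:
        return sorted({s.group for s in self.samples})

    def group_indices(self, group: str) -> np.ndarray:
        idx = np.array(
            [i for i, s in enumerate(self.samples) if s.group == group],
            dtype=np.intp,
        )
        if idx.size == 0:
            raise KeyError(f"no samples in group {group!r}")
        return idx

    def group_ids(self, group: str) -> list[str]:
        return [self.samples[i].id for i in self.group_indices(group)]

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def site_mask(self, window: Window) -> np.ndarray:
        """Boolean site mask for a 0-based half-open window (pos is 1-based)."""
        return (
            (self.chrom == window.chrom)
            & (self.pos - 1 >= window.start)
            & (self.pos - 1 < window.end)
        )

    def subset(
        self,
        sample_idx: np.ndarray | None = None,
        site_idx: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        samples = self.samples
        calls = self.calls
        chrom, pos, ref, alt = self.chrom, self.pos, self.ref, self.alt
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            samples = [self.samples[i] for i in sample_idx]
            calls = calls[sample_idx, :]
        if site_idx is not None:
            site_idx = np.asarray(site_idx)
            calls = calls[:, site_idx]
            chrom, pos = chrom[site_idx], pos[site_idx]
            ref, alt = ref[site_idx], alt[site_idx]
        return GenotypeMatrix(samples, chrom, pos, ref, alt, calls)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GenotypeMatrix({self.n_samples} samples x {self.n_sites} sites, "
            f"groups={self.groups})"
        )


def tile_windows(
    chrom_lengths: dict[str, int], size: int, step: int | None = None
) -> list[Window]:
    """Tile each chromosome with windows of ``size`` bp.

    ``step=None`` gives non-overlapping windows; a smaller step gives a
    sliding grid.  The last window is truncated at the chromosome end.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    step = size if step is None else step
    if step <= 0:
        raise ValueError("window step must be positive")
    out: list[Window] = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            out.append(Window(chrom, start, min(start + size, length)))
            start += step
    return out
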