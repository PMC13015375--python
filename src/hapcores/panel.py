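"""Haplotype panels, site coordinates, and genomic length arithmetic.

A panel is a binary M x N allele matrix (rows = haplotypes, columns =
variant sites) together with per-site physical positions (bp) and, when a
genetic map is available, genetic positions (cM).  Site indices are
0-based and all intervals are half-open ``[s, e)``: sites ``s .. e-1``.

Physical/genetic length of an interval ``[s, e)`` is measured from site
``s`` to site ``e - 1`` — the last site actually covered — because site
``e`` lies outside the interval.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np


class PanelFormatError(ValueError):
    """Malformed panel input (non-binary alleles, multiallelic site, ...)."""


class PhaseError(PanelFormatError):
    """Unphased genotype encountered where phased haplotypes are required."""


class CoordinateError(ValueError):
    """Non-monotone or otherwise invalid site coordinates."""


UNITS = ("sites", "bp", "cm")


@dataclasses.dataclass(frozen=True)
class SiteInterval:
    """Half-open site interval [s, e), 0 <= s < e."""

    s: int
    e: int

    def __post_init__(self) -> None:
        if not (0 <= self.s < self.e):
            raise ValueError(f"invalid site interval [{self.s}, {self.e})")

    def __len__(self) -> int:
        return self.e - self.s


@dataclasses.dataclass
class HaplotypePanel:
    """Phased binary haplotype panel.

    Attributes
    ----------
    alleles : ndarray of uint8, shape (M, N)
        Binary allele matrix; row i is haplotype i.
    site_bp : ndarray of int64, shape (N,)
        Physical position of each site, strictly increasing.
    site_cm : ndarray of float64, shape (N,), optional
        Genetic position of each site (non-decreasing), or None.
    sample_ids : list of str
        One unique identifier per haplotype row.
    """

    alleles: np.ndarray
    site_bp: np.ndarray
    site_cm: np.ndarray | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] < 1 or self.alleles.shape[1] < 1:
            raise PanelFormatError("allele matrix must be 2-D with M >= 1, N >= 1")
        if not np.isin(self.alleles, (0, 1)).all():
            raise PanelFormatError("allele values must be 0 or 1")
        self.site_bp = np.asarray(self.site_bp, dtype=np.int64)
        if self.site_bp.shape != (self.N,):
            raise CoordinateError("site_bp length must equal the number of sites")
        if np.any(np.diff(self.site_bp) <= 0):
            raise CoordinateError("site_bp must be strictly increasing")
        if self.site_cm is not None:
            self.site_cm = np.asarray(self.site_cm, dtype=np.float64)
            if self.site_cm.shape != (self.N,):
                raise CoordinateError("site_cm length must equal the number of sites")
            if np.any(np.diff(self.site_cm) < 0):
                raise CoordinateError("site_cm must be non-decreasing")
        if self.sample_ids is None:
            self.sample_ids = [f"hap{i}" for i in range(self.M)]
        if len(self.sample_ids) != self.M:
            raise PanelFormatError("sample_ids length must equal the number of haplotypes")
        if len(set(self.sample_ids)) != self.M:
            raise PanelFormatError("sample_ids must be unique")

    @property
    def M(self) -> int:
        return self.alleles.shape[0]

    @property
    def N(self) -> int:
        return self.alleles.shape[1]


def _as_interval(iv) -> tuple[int, int]:
    if isinstance(iv, SiteInterval):
        return iv.s, iv.e
    s, e = iv
    return int(s), int(e)


def interval_length(panel: HaplotypePanel | None, iv, unit: str = "sites") -> float:
    """Length of half-open interval [s, e) in sites, bp, or cM.

    ``sites`` is the site count ``e - s``; ``bp``/``cm`` span from site s to
    site e-1 (the last covered site).  For unit='sites' the panel may be None.
    """
    s, e = _as_interval(iv)
    if not 0 <= s < e:
        raise ValueError(f"invalid interval [{s}, {e})")
    if unit == "sites":
        return float(e - s)
    if panel is None:
        raise ValueError(f"unit {unit!r} requires a panel with coordinates")
    if e > panel.N:
        raise ValueError("interval end beyond panel")
    if unit == "bp":
        return float(panel.site_bp[e - 1] - panel.site_bp[s])
    if unit == "cm":
        if panel.site_cm is None:
            raise ValueError("unit 'cm' requires a genetic map (site_cm is missing)")
        return float(panel.site_cm[e - 1] - panel.site_cm[s])
    raise ValueError(f"unknown unit {unit!r}; expected one of {UNITS}")


# ---------------------------------------------------------------------------
# genetic map


def read_genetic_map(path) -> np.ndarray:
    """Read a two-column whitespace-separated (bp, cM) map; '#' comments."""
    gmap = np.loadtxt(path, comments="#", ndmin=2, dtype=np.float64)
    if gmap.size == 0:
        raise CoordinateError("empty genetic map")
    if gmap.shape[1] < 2:
        raise CoordinateError("genetic map needs two columns: bp cM")
    return gmap[:, :2]


def attach_genetic_map(panel: HaplotypePanel, gmap) -> HaplotypePanel:
    """Return a copy of the panel with site_cm interpolated from (bp, cM) pairs.

    Linear interpolation between flanking map points; sites outside the map
    range take the boundary cM value (clamped extrapolation).
    """
    gmap = np.asarray(gmap, dtype=np.float64)
    if gmap.ndim != 2 or gmap.shape[0] == 0:
        raise CoordinateError("empty genetic map")
    bp, cm = gmap[:, 0], gmap[:, 1]
    if np.any(np.diff(bp) <= 0):
        raise CoordinateError("genetic map bp must be strictly increasing")
    if np.any(np.diff(cm) < 0):
        raise CoordinateError("genetic map cM must be non-decreasing")
    site_cm = np.interp(panel.site_bp, bp, cm)  # np.interp clamps at the ends
    return dataclasses.replace(panel, site_cm=site_cm)


# ---------------------------------------------------------------------------
# panel input / output


def read_panel(path, format: str = "auto") -> HaplotypePanel:
    """Load a panel from a phased biallelic VCF or the plain matrix format."""
    path = Path(path)
    if format == "auto":
        name = path.name.lower()
        format = "vcf" if (".vcf" in name or name.endswith(".bcf")) else "matrix"
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown panel format {format!r}")


def _read_matrix(path: Path) -> HaplotypePanel:
    """Plain matrix: '#BP <ints>', optional '#CM <reals>', then 0/1 rows."""
    site_bp = None
    site_cm = None
    rows: list[str] = []
    ids: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#BP"):
                site_bp = [int(v) for v in line.split()[1:]]
            elif line.startswith("#CM"):
                site_cm = [float(v) for v in line.split()[1:]]
            elif line.startswith("#"):
                continue
            else:
                fields = line.split()
                if len(fields) == 2:
                    ids.append(fields[0])
                    seq = fields[1]
                elif len(fields) == 1:
                    seq = fields[0]
                else:
                    raise PanelFormatError(f"{path}:{lineno}: expected '[id] 01-string'")
                if set(seq) - {"0", "1"}:
                    raise PanelFormatError(f"{path}:{lineno}: non-binary allele in row")
                rows.append(seq)
    if not rows:
        raise PanelFormatError(f"{path}: no haplotype rows")
    if site_bp is None:
        raise PanelFormatError(f"{path}: missing '#BP' header line")
    if len({len(r) for r in rows}) != 1:
        raise PanelFormatError(f"{path}: ragged haplotype rows")
    alleles = np.array([[int(c) for c in r] for r in rows], dtype=np.uint8)
    return HaplotypePanel(
        alleles=alleles,
        site_bp=np.asarray(site_bp),
        site_cm=None if site_cm is None else np.asarray(site_cm),
        sample_ids=ids if ids else None,
    )


def write_matrix(panel: HaplotypePanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("#BP " + " ".join(str(int(v)) for v in panel.site_bp) + "\n")
        if panel.site_cm is not None:
            fh.write("#CM " + " ".join(format(v, "g") for v in panel.site_cm) + "\n")
        for i in range(panel.M):
            row = "".join("1" if v else "0" for v in panel.alleles[i])
            fh.write(f"{panel.sample_ids[i]} {row}\n")


def _read_vcf(path: Path) -> HaplotypePanel:
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise PanelFormatError(f"{path}: VCF has no samples")
        columns: list[list[int]] = []
        site_bp: list[int] = []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise PanelFormatError(
                    f"{path}: site at pos {rec.pos} is not biallelic"
                )
            col: list[int] = []
            for sample in samples:
                call = rec.samples[sample]
                gt = call["GT"]
                if gt is None or len(gt) != 2:
                    raise PanelFormatError(
                        f"{path}: sample {sample} at pos {rec.pos} is not diploid"
                    )
                if gt[0] is None or gt[1] is None:
                    raise PanelFormatError(
                        f"{path}: missing allele for {sample} at pos {rec.pos}"
                    )
                if not call.phased:
                    raise PhaseError(
                        f"{path}: unphased genotype for {sample} at pos {rec.pos}"
                    )
                if gt[0] not in (0, 1) or gt[1] not in (0, 1):
                    raise PanelFormatError(
                        f"{path}: non-binary allele for {sample} at pos {rec.pos}"
                    )
                col.extend((gt[0], gt[1]))
            site_bp.append(rec.pos)
            columns.append(col)
    if not columns:
        raise PanelFormatError(f"{path}: VCF has no variant records")
    if any(b - a <= 0 for a, b in zip(site_bp, site_bp[1:])):
        raise CoordinateError(f"{path}: VCF positions not strictly increasing")
    alleles = np.array(columns, dtype=np.uint8).T  # (2*samples, N)
    ids = [f"{s}_{h}" for s in samples for h in (0, 1)]
    return HaplotypePanel(alleles=alleles, site_bp=np.asarray(site_bp), sample_ids=ids)
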