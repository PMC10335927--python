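"""Sparse reference-panel storage, the genetic map, and the binary panel format.

A phased biallelic reference panel is stored one column per variant site.
Columns at common sites (panel MAF >= ``maf_threshold``) keep one bit per
haplotype; columns at rare sites keep only the sorted indices of the
haplotypes carrying the minor allele.  The transpose of the rare columns
(per-haplotype lists of carried rare sites) is maintained alongside, giving
direct access to the rare variants of each haplotype.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BITS",
    "CARRIER_LIST",
    "DEFAULT_MAF_THRESHOLD",
    "VariantSite",
    "SparseColumn",
    "HaplotypePanel",
    "GeneticMap",
    "build_sparse_panel",
    "read_genetic_map",
    "write_binary_panel",
    "read_binary_panel",
    "PanelFormatError",
    "PanelVersionError",
]

BITS = "bits"
CARRIER_LIST = "carriers"
DEFAULT_MAF_THRESHOLD = 0.001

_MAGIC = b"SIMP"
_VERSION = 1


class PanelFormatError(ValueError):
    """Raised when a binary panel file is malformed or truncated."""


class PanelVersionError(PanelFormatError):
    """Raised when a binary panel file has an unsupported version."""


@dataclass
class VariantSite:
    """One biallelic marker of the panel.

    ``pos_bp`` is 0-based internally; VCF I/O converts at the boundary.
    ``cm`` is the interpolated genetic position in centimorgans.
    """

    chrom: str
    pos_bp: int
    ref: str
    alt: str
    is_snp: bool = True
    alt_count: int = 0
    cm: float = 0.0

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(
                f"site {self.chrom}:{self.pos_bp + 1} has ref == alt ({self.ref!r})"
            )


@dataclass
class SparseColumn:
    """Sparse encoding of one panel column.

    encoding == BITS
        ``bits`` holds the ALT-allele indicator for every haplotype.
    encoding == CARRIER_LIST
        ``carriers`` holds the sorted indices of minor-allele carriers;
        ``minor_is_alt`` says which allele the carriers hold.
    """

    encoding: str
    minor_is_alt: bool
    bits: np.ndarray | None = None
    carriers: np.ndarray | None = None

    def alleles(self, n_hap: int) -> np.ndarray:
        """Dense ALT-allele indicator vector for this column."""
        if self.encoding == BITS:
            return self.bits.astype(np.uint8)
        base = 0 if self.minor_is_alt else 1
        out = np.full(n_hap, base, dtype=np.uint8)
        out[self.carriers] = 1 - base
        return out

    def minor_mask(self, n_hap: int) -> np.ndarray:
        """Boolean vector: does each haplotype carry the minor allele?"""
        if self.encoding == BITS:
            return self.bits == (1 if self.minor_is_alt else 0)
        out = np.zeros(n_hap, dtype=bool)
        out[self.carriers] = True
        return out


class HaplotypePanel:
    """Sparse column store plus its per-haplotype transpose."""

    def __init__(
        self,
        sites: list[VariantSite],
        n_hap: int,
        columns: list[SparseColumn],
        maf_threshold: float = DEFAULT_MAF_THRESHOLD,
        transpose: list[np.ndarray] | None = None,
    ) -> None:
        if len(sites) != len(columns):
            raise ValueError("sites and columns length mismatch")
        self.sites = sites
        self.n_hap = int(n_hap)
        self.columns = columns
        self.maf_threshold = float(maf_threshold)
        self.transpose = (
            transpose if transpose is not None else self._build_transpose()
        )
        self._dense: np.ndarray | None = None
        self._minorized: np.ndarray | None = None

    # -- construction helpers -------------------------------------------------

    def _build_transpose(self) -> list[np.ndarray]:
        per_hap: list[list[int]] = [[] for _ in range(self.n_hap)]
        for s, col in enumerate(self.columns):
            if col.encoding == CARRIER_LIST:
                for h in col.carriers:
                    per_hap[int(h)].append(s)
        return [np.asarray(v, dtype=np.int64) for v in per_hap]

    # -- basic accessors ------------------------------------------------------

    @property
    def n_site(self) -> int:
        return len(self.sites)

    def is_common(self, site: int) -> bool:
        return self.columns[site].encoding == BITS

    @property
    def common_sites(self) -> np.ndarray:
        return np.asarray(
            [s for s in range(self.n_site) if self.is_common(s)], dtype=np.int64
        )

    def alt_count(self, site: int) -> int:
        return self.sites[site].alt_count

    def maf(self, site: int) -> float:
        ac = self.sites[site].alt_count
        return min(ac, self.n_hap - ac) / self.n_hap

    def alt_freq(self, site: int) -> float:
        return self.sites[site].alt_count / self.n_hap

    @property
    def cm_positions(self) -> np.ndarray:
        return np.asarray([s.cm for s in self.sites], dtype=np.float64)

    def get_allele(self, hap: int, site: int) -> int:
        """ALT-allele indicator for one (haplotype, site) cell."""
        if not (0 <= hap < self.n_hap):
            raise IndexError(f"haplotype index {hap} out of range [0, {self.n_hap})")
        if not (0 <= site < self.n_site):
            raise IndexError(f"site index {site} out of range [0, {self.n_site})")
        col = self.columns[site]
        if col.encoding == BITS:
            return int(col.bits[hap])
        carried = bool(np.searchsorted(col.carriers, hap) < len(col.carriers)) and (
            col.carriers[np.searchsorted(col.carriers, hap)] == hap
        )
        if col.minor_is_alt:
            return 1 if carried else 0
        return 0 if carried else 1

    def site_alleles(self, site: int) -> np.ndarray:
        return self.columns[site].alleles(self.n_hap)

    def minor_mask(self, site: int) -> np.ndarray:
        return self.columns[site].minor_mask(self.n_hap)

    def dense(self) -> np.ndarray:
        """Dense (n_site, n_hap) ALT-indicator matrix (cached)."""
        if self._dense is None:
            out = np.empty((self.n_site, self.n_hap), dtype=np.uint8)
            for s, col in enumerate(self.columns):
                out[s] = col.alleles(self.n_hap)
            self._dense = out
        return self._dense

    def minorized(self) -> np.ndarray:
        """Dense (n_site, n_hap) minor-allele indicator matrix (cached)."""
        if self._minorized is None:
            dense = self.dense()
            flip = np.asarray(
                [0 if c.minor_is_alt else 1 for c in self.columns], dtype=np.uint8
            )
            self._minorized = dense ^ flip[:, None]
        return self._minorized

    def storage_cost_bytes(self) -> int:
        """Accounting cost of the column store: N/8 bytes per common site
        plus one index per stored carrier (4 bytes)."""
        total = 0
        for col in self.columns:
            if col.encoding == BITS:
                total += (self.n_hap + 7) // 8
            else:
                total += 4 * len(col.carriers)
        return total


def build_sparse_panel(
    phased_haplotypes,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    sites: list[VariantSite] | None = None,
) -> HaplotypePanel:
    """Build the sparse panel from dense per-site allele vectors.

    Parameters
    ----------
    phased_haplotypes:
        Sequence of per-site allele vectors (each of length ``n_hap``,
        values in {0, 1}), or an equivalent (n_site, n_hap) array.
    maf_threshold:
        Sites with minor-allele frequency >= this value are bit-encoded
        (ties included); rarer sites store carrier lists.
    sites:
        Optional site metadata; synthesized if omitted.
    """
    rows = list(phased_haplotypes)
    if rows:
        n_hap = len(rows[0])
        for i, r in enumerate(rows):
            if len(r) != n_hap:
                raise ValueError(
                    f"ragged haplotype vectors: site 0 has {n_hap} alleles, "
                    f"site {i} has {len(r)}"
                )
        dense = np.asarray(rows, dtype=np.int64)
    else:
        n_hap = 0
        dense = np.zeros((0, 0), dtype=np.int64)
    if dense.size and not np.isin(dense, (0, 1)).all():
        bad = int(np.where(~np.isin(dense, (0, 1)).all(axis=1))[0][0])
        ident = (
            f"{sites[bad].chrom}:{sites[bad].pos_bp + 1}" if sites else f"site {bad}"
        )
        raise ValueError(f"non-biallelic record at {ident}: alleles outside {{0,1}}")

    n_site = dense.shape[0]
    if sites is None:
        sites = [
            VariantSite(chrom="1", pos_bp=s, ref="A", alt="C") for s in range(n_site)
        ]
    elif len(sites) != n_site:
        raise ValueError("sites metadata length mismatch")

    columns: list[SparseColumn] = []
    for s in range(n_site):
        alt_count = int(dense[s].sum())
        sites[s].alt_count = alt_count
        minor_count = min(alt_count, n_hap - alt_count)
        minor_is_alt = alt_count <= n_hap - alt_count
        maf = minor_count / n_hap if n_hap else 0.0
        if n_hap and maf >= maf_threshold:
            columns.append(
                SparseColumn(
                    encoding=BITS,
                    minor_is_alt=minor_is_alt,
                    bits=dense[s].astype(np.uint8),
                )
            )
        else:
            minor_val = 1 if minor_is_alt else 0
            carriers = np.flatnonzero(dense[s] == minor_val).astype(np.int64)
            columns.append(
                SparseColumn(
                    encoding=CARRIER_LIST, minor_is_alt=minor_is_alt, carriers=carriers
                )
            )
    return HaplotypePanel(sites, n_hap, columns, maf_threshold)


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Piecewise-linear genetic map given as (pos_bp, cm) anchors."""

    pos_bp: np.ndarray
    cm: np.ndarray
    extrapolation_rate_cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if self.pos_bp.size != self.cm.size:
            raise ValueError("anchor arrays differ in length")
        if self.pos_bp.size and np.any(np.diff(self.pos_bp) <= 0):
            raise ValueError("anchor positions must be strictly increasing")
        if self.cm.size and np.any(np.diff(self.cm) < 0):
            raise ValueError("anchor cm values must be non-decreasing")

    @classmethod
    def uniform(cls, region_bp: int, rate_cm_per_mb: float = 1.0) -> "GeneticMap":
        return cls(
            pos_bp=np.asarray([0, region_bp], dtype=np.int64),
            cm=np.asarray([0.0, region_bp * rate_cm_per_mb * 1e-6]),
            extrapolation_rate_cm_per_mb=rate_cm_per_mb,
        )

    def interpolate_cm(self, pos_bp):
        """cM at ``pos_bp`` (scalar or array), linear between anchors and
        extrapolated at a constant rate beyond them."""
        if self.pos_bp.size == 0:
            raise ValueError("cannot interpolate with an empty genetic map")
        pos = np.asarray(pos_bp, dtype=np.float64)
        rate = self.extrapolation_rate_cm_per_mb * 1e-6
        out = np.interp(pos, self.pos_bp, self.cm)
        lo, hi = self.pos_bp[0], self.pos_bp[-1]
        out = np.where(pos < lo, self.cm[0] - (lo - pos) * rate, out)
        out = np.where(pos > hi, self.cm[-1] + (pos - hi) * rate, out)
        if np.isscalar(pos_bp) or np.ndim(pos_bp) == 0:
            return float(out)
        return out


def interpolate_cm(gmap: GeneticMap, pos_bp):
    return gmap.interpolate_cm(pos_bp)


def read_genetic_map(path) -> GeneticMap:
    """Read a whitespace-delimited map file: one header line, then
    columns position(bp), rate(cM/Mb), map(cM)."""
    pos, cm = [], []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            pos.append(int(parts[0]))
            cm.append(float(parts[2]))
    return GeneticMap(np.asarray(pos), np.asarray(cm))


def annotate_cm(panel: HaplotypePanel, gmap: GeneticMap) -> None:
    """Fill every site's cm field from the map (in place)."""
    cms = gmap.interpolate_cm(np.asarray([s.pos_bp for s in panel.sites]))
    cms = np.atleast_1d(cms)
    for site, c in zip(panel.sites, cms):
        site.cm = float(c)


# ---------------------------------------------------------------------------
# Binary panel file
# ---------------------------------------------------------------------------
# Layout (little-endian, no general-purpose compression):
#   magic "SIMP" | u32 version | u64 n_hap | u64 n_site | f64 maf_threshold
#   chromosome table, site table, column blocks,
#   RLE-encoded PBWT checkpoint blocks, map anchors.


def _rle_encode_perm(perm: np.ndarray) -> bytes:
    """First value + run-length-encoded successive deltas."""
    perm = np.asarray(perm, dtype=np.int64)
    out = [struct.pack("<q", int(perm[0]) if perm.size else 0)]
    if perm.size <= 1:
        out.append(struct.pack("<I", 0))
        return b"".join(out)
    deltas = np.diff(perm)
    change = np.flatnonzero(np.diff(deltas) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(deltas)]))
    out.append(struct.pack("<I", len(starts)))
    for a, b in zip(starts, ends):
        out.append(struct.pack("<qI", int(deltas[a]), int(b - a)))
    return b"".join(out)


def _rle_decode_perm(buf: memoryview, off: int) -> tuple[np.ndarray, int]:
    (first,) = struct.unpack_from("<q", buf, off)
    off += 8
    (n_runs,) = struct.unpack_from("<I", buf, off)
    off += 4
    deltas = []
    for _ in range(n_runs):
        d, n = struct.unpack_from("<qI", buf, off)
        off += 12
        deltas.append(np.full(n, d, dtype=np.int64))
    if deltas:
        vals = np.concatenate(([first], first + np.cumsum(np.concatenate(deltas))))
    else:
        vals = np.asarray([first], dtype=np.int64)
    return vals, off


def _pack_str(s: str) -> bytes:
    b = s.encode()
    return struct.pack("<H", len(b)) + b


def _unpack_str(buf: memoryview, off: int) -> tuple[str, int]:
    (n,) = struct.unpack_from("<H", buf, off)
    off += 2
    return bytes(buf[off : off + n]).decode(), off + n


def write_binary_panel(panel: HaplotypePanel, checkpoints, gmap: GeneticMap, path) -> None:
    """Serialize panel + PBWT checkpoints + genetic map to one binary file."""
    parts: list[bytes] = [
        _MAGIC,
        struct.pack("<IQQd", _VERSION, panel.n_hap, panel.n_site, panel.maf_threshold),
    ]
    chroms: list[str] = []
    chrom_id: dict[str, int] = {}
    for site in panel.sites:
        if site.chrom not in chrom_id:
            chrom_id[site.chrom] = len(chroms)
            chroms.append(site.chrom)
    parts.append(struct.pack("<I", len(chroms)))
    parts.extend(_pack_str(c) for c in chroms)
    for site in panel.sites:
        parts.append(
            struct.pack(
                "<IQBQd",
                chrom_id[site.chrom],
                site.pos_bp,
                1 if site.is_snp else 0,
                site.alt_count,
                site.cm,
            )
        )
        parts.append(_pack_str(site.ref))
        parts.append(_pack_str(site.alt))
    for col in panel.columns:
        if col.encoding == BITS:
            parts.append(struct.pack("<BB", 0, 1 if col.minor_is_alt else 0))
            parts.append(np.packbits(col.bits.astype(np.uint8)).tobytes())
        else:
            parts.append(struct.pack("<BB", 1, 1 if col.minor_is_alt else 0))
            parts.append(struct.pack("<Q", len(col.carriers)))
            parts.append(col.carriers.astype("<u4").tobytes())
    cp_sites = np.asarray(checkpoints.checkpoint_sites, dtype=np.int64)
    parts.append(struct.pack("<Q", len(cp_sites)))
    parts.append(cp_sites.astype("<i8").tobytes())
    for arr in checkpoints.prefix_arrays:
        parts.append(_rle_encode_perm(arr))
    parts.append(struct.pack("<Qd", gmap.pos_bp.size, gmap.extrapolation_rate_cm_per_mb))
    parts.append(gmap.pos_bp.astype("<i8").tobytes())
    parts.append(gmap.cm.astype("<f8").tobytes())
    with open(path, "wb") as fh:
        fh.write(b"".join(parts))


def read_binary_panel(path):
    """Lossless inverse of :func:`write_binary_panel`.

    Returns (HaplotypePanel, PbwtCheckpoints, GeneticMap).
    """
    from .sparse_pbwt import PbwtCheckpoints  # local import avoids a cycle

    with open(path, "rb") as fh:
        raw = fh.read()
    buf = memoryview(raw)
    try:
        if bytes(buf[:4]) != _MAGIC:
            raise PanelFormatError(f"bad magic bytes in {path!s}")
        version, n_hap, n_site, maf_threshold = struct.unpack_from("<IQQd", buf, 4)
        if version != _VERSION:
            raise PanelVersionError(
                f"unsupported panel file version {version} (expected {_VERSION})"
            )
        off = 4 + struct.calcsize("<IQQd")
        (n_chroms,) = struct.unpack_from("<I", buf, off)
        off += 4
        chroms = []
        for _ in range(n_chroms):
            c, off = _unpack_str(buf, off)
            chroms.append(c)
        sites: list[VariantSite] = []
        for _ in range(n_site):
            cid, pos_bp, is_snp, alt_count, cm = struct.unpack_from("<IQBQd", buf, off)
            off += struct.calcsize("<IQBQd")
            ref, off = _unpack_str(buf, off)
            alt, off = _unpack_str(buf, off)
            sites.append(
                VariantSite(
                    chrom=chroms[cid],
                    pos_bp=int(pos_bp),
                    ref=ref,
                    alt=alt,
                    is_snp=bool(is_snp),
                    alt_count=int(alt_count),
                    cm=float(cm),
                )
            )
        nbytes_bits = (n_hap + 7) // 8
        columns: list[SparseColumn] = []
        for _ in range(n_site):
            enc, mia = struct.unpack_from("<BB", buf, off)
            off += 2
            if enc == 0:
                bits = np.unpackbits(
                    np.frombuffer(buf, dtype=np.uint8, count=nbytes_bits, offset=off)
                )[:n_hap]
                off += nbytes_bits
                columns.append(
                    SparseColumn(encoding=BITS, minor_is_alt=bool(mia), bits=bits)
                )
            else:
                (n_car,) = struct.unpack_from("<Q", buf, off)
                off += 8
                carriers = np.frombuffer(
                    buf, dtype="<u4", count=n_car, offset=off
                ).astype(np.int64)
                off += 4 * n_car
                columns.append(
                    SparseColumn(
                        encoding=CARRIER_LIST, minor_is_alt=bool(mia), carriers=carriers
                    )
                )
        (n_cp,) = struct.unpack_from("<Q", buf, off)
        off += 8
        cp_sites = np.frombuffer(buf, dtype="<i8", count=n_cp, offset=off).copy()
        off += 8 * n_cp
        arrays = []
        for _ in range(n_cp):
            arr, off = _rle_decode_perm(buf, off)
            arrays.append(arr[:n_hap] if n_hap else np.asarray([], dtype=np.int64))
        n_anchor, rate = struct.unpack_from("<Qd", buf, off)
        off += struct.calcsize("<Qd")
        map_pos = np.frombuffer(buf, dtype="<i8", count=n_anchor, offset=off).copy()
        off += 8 * n_anchor
        map_cm = np.frombuffer(buf, dtype="<f8", count=n_anchor, offset=off).copy()
        off += 8 * n_anchor
    except (struct.error, IndexError) as exc:
        raise PanelFormatError(f"truncated or corrupt panel file {path!s}") from exc
    panel = HaplotypePanel(sites, int(n_hap), columns, float(maf_threshold))
    checkpoints = PbwtCheckpoints(checkpoint_sites=cp_sites, prefix_arrays=arrays)
    gmap = GeneticMap(map_pos, map_cm, extrapolation_rate_cm_per_mb=float(rate))
    return panel, checkpoints, gmap
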