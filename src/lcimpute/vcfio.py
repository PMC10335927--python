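"""VCF input/output.

Readers are backed by cyvcf2/htslib; writers emit plain uncompressed VCF
text with fixed number formatting so identical runs produce byte-identical
files.  Positions are 1-based in files and 0-based in memory.
"""

from __future__ import annotations

import numpy as np
from cyvcf2 import VCF

from .imputation_engine import Diplotype, PosteriorRecord
from .panel_store import (
    DEFAULT_MAF_THRESHOLD,
    GeneticMap,
    HaplotypePanel,
    VariantSite,
    annotate_cm,
    build_sparse_panel,
)

__all__ = [
    "site_key",
    "write_panel_vcf",
    "read_panel_vcf",
    "write_gl_vcf",
    "read_gl_vcf",
    "write_truth_vcf",
    "read_truth_vcf",
    "write_imputed_vcf",
    "read_imputed_vcf",
    "align_gl_to_panel",
]


def site_key(chrom: str, pos_bp0: int, ref: str, alt: str) -> tuple:
    return (str(chrom), int(pos_bp0), str(ref), str(alt))


def _header(samples, chroms, extra_lines=()) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=lcimpute"]
    for c in dict.fromkeys(chroms):
        lines.append(f"##contig=<ID={c}>")
    lines.extend(extra_lines)
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    cols.extend(samples)
    lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


# -- reference panel ---------------------------------------------------------


def write_panel_vcf(panel: HaplotypePanel, path, sample_prefix: str = "REF") -> None:
    """Phased panel haplotypes as diploid GT columns."""
    n_sample = panel.n_hap // 2
    samples = [f"{sample_prefix}{i:04d}" for i in range(n_sample)]
    extra = ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    with open(path, "w") as fh:
        fh.write(_header(samples, [s.chrom for s in panel.sites], extra))
        for s in range(panel.n_site):
            site = panel.sites[s]
            alleles = panel.site_alleles(s)
            gts = "\t".join(
                f"{alleles[2 * i]}|{alleles[2 * i + 1]}" for i in range(n_sample)
            )
            fh.write(
                f"{site.chrom}\t{site.pos_bp + 1}\t.\t{site.ref}\t{site.alt}\t.\t"
                f"PASS\t.\tGT\t{gts}\n"
            )


def read_panel_vcf(
    path,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    gmap: GeneticMap | None = None,
) -> HaplotypePanel:
    """Read a phased reference VCF into the sparse panel representation.

    Multiallelic records and unphased genotypes are rejected.
    """
    vcf = VCF(str(path))
    rows = []
    sites: list[VariantSite] = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {v.CHROM}:{v.POS}; split to biallelic upstream"
            )
        gts = v.genotypes
        alleles = np.empty(2 * len(gts), dtype=np.int64)
        for i, g in enumerate(gts):
            if len(g) < 3 or not g[2]:
                raise ValueError(f"unphased genotype at {v.CHROM}:{v.POS}")
            alleles[2 * i] = g[0]
            alleles[2 * i + 1] = g[1]
        rows.append(alleles)
        sites.append(
            VariantSite(
                chrom=v.CHROM,
                pos_bp=v.POS - 1,
                ref=v.REF,
                alt=v.ALT[0],
                is_snp=len(v.REF) == 1 and len(v.ALT[0]) == 1,
            )
        )
    panel = build_sparse_panel(rows, maf_threshold, sites=sites)
    if gmap is not None:
        annotate_cm(panel, gmap)
    return panel


# -- genotype likelihoods ----------------------------------------------------


def write_gl_vcf(path, sites, gl, samples, fmt: str = "PL") -> None:
    """Target genotype likelihoods; ``gl`` is (n_sample, n_site, 3) linear."""
    gl = np.asarray(gl, dtype=np.float64)
    extra = [
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">'
        if fmt == "PL"
        else '##FORMAT=<ID=GL,Number=G,Type=Float,Description="log10 genotype likelihoods">'
    ]
    with open(path, "w") as fh:
        fh.write(_header(samples, [s.chrom for s in sites], extra))
        for m, site in enumerate(sites):
            cols = []
            for i in range(len(samples)):
                trip = gl[i, m]
                trip = trip / trip.max()
                if fmt == "PL":
                    with np.errstate(divide="ignore"):
                        pl = np.minimum(np.round(-10 * np.log10(trip)), 255)
                    pl = np.where(np.isfinite(pl), pl, 255).astype(int)
                    cols.append(",".join(str(int(x)) for x in pl))
                else:
                    with np.errstate(divide="ignore"):
                        lg = np.maximum(np.log10(trip), -25.5)
                    cols.append(",".join(f"{x:.4f}" for x in lg))
            fh.write(
                f"{site.chrom}\t{site.pos_bp + 1}\t.\t{site.ref}\t{site.alt}\t.\t"
                f"PASS\t.\t{fmt}\t" + "\t".join(cols) + "\n"
            )


def read_gl_vcf(path):
    """Returns (keys, samples, gl) with gl (n_sample, n_site, 3) linear,
    max-normalized; PL (phred) and GL (log10) are both accepted."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    keys = []
    triplets = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"multiallelic record at {v.CHROM}:{v.POS}")
        keys.append(site_key(v.CHROM, v.POS - 1, v.REF, v.ALT[0]))
        try:
            pl = v.format("PL")
        except KeyError:
            pl = None
        if pl is not None:
            lin = 10.0 ** (-np.asarray(pl, dtype=np.float64) / 10.0)
        else:
            try:
                g = v.format("GL")
            except KeyError:
                g = None
            if g is None:
                raise ValueError(f"no PL or GL field at {v.CHROM}:{v.POS}")
            lin = 10.0 ** np.asarray(g, dtype=np.float64)
        lin = np.where(np.isfinite(lin), lin, 0.0)
        mx = lin.max(axis=1, keepdims=True)
        mx[mx <= 0] = 1.0
        triplets.append(lin / mx)
    gl = (
        np.stack(triplets, axis=1)
        if triplets
        else np.zeros((len(samples), 0, 3))
    )
    return keys, samples, gl


def align_gl_to_panel(panel: HaplotypePanel, keys, gl) -> np.ndarray:
    """Map GL rows onto panel sites by (chrom, pos, ref, alt); sites absent
    from the GL input get the flat uninformative triplet."""
    index = {k: i for i, k in enumerate(keys)}
    n_sample = gl.shape[0]
    out = np.ones((n_sample, panel.n_site, 3))
    for s, site in enumerate(panel.sites):
        i = index.get(site_key(site.chrom, site.pos_bp, site.ref, site.alt))
        if i is not None:
            out[:, s, :] = gl[:, i, :]
    return out


# -- truth genotypes ---------------------------------------------------------


def write_truth_vcf(path, sites, diplotypes: list[Diplotype], samples) -> None:
    extra = ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    with open(path, "w") as fh:
        fh.write(_header(samples, [s.chrom for s in sites], extra))
        for m, site in enumerate(sites):
            gts = "\t".join(
                f"{int(d.hap1[m])}|{int(d.hap2[m])}" for d in diplotypes
            )
            fh.write(
                f"{site.chrom}\t{site.pos_bp + 1}\t.\t{site.ref}\t{site.alt}\t.\t"
                f"PASS\t.\tGT\t{gts}\n"
            )


def read_truth_vcf(path):
    """Returns (keys, samples, gt) with gt (n_sample, n_site, 2)."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    keys = []
    rows = []
    for v in vcf:
        keys.append(site_key(v.CHROM, v.POS - 1, v.REF, v.ALT[0]))
        rows.append([[g[0], g[1]] for g in v.genotypes])
    gt = (
        np.asarray(rows, dtype=np.int8).transpose(1, 0, 2)
        if rows
        else np.zeros((len(samples), 0, 2), dtype=np.int8)
    )
    return keys, samples, gt


# -- imputed output ----------------------------------------------------------


def write_imputed_vcf(
    path, panel: HaplotypePanel, records: list[PosteriorRecord], samples
) -> None:
    """Imputed calls: phased GT, dosage DS, genotype posteriors GP, and the
    panel alternate-allele frequency as INFO/RAF."""
    if len(records) != len(samples):
        raise ValueError("one PosteriorRecord per sample required")
    site_idx = records[0].site_indices
    for r in records[1:]:
        if not np.array_equal(r.site_indices, site_idx):
            raise ValueError("records cover different site sets")
    extra = [
        '##INFO=<ID=RAF,Number=A,Type=Float,Description="Reference panel ALT allele frequency">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased best-guess genotype">',
        '##FORMAT=<ID=DS,Number=A,Type=Float,Description="Imputed ALT dosage">',
        '##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype posteriors">',
    ]
    chroms = [panel.sites[int(s)].chrom for s in site_idx]
    with open(path, "w") as fh:
        fh.write(_header(samples, chroms, extra))
        for j, s in enumerate(site_idx):
            site = panel.sites[int(s)]
            raf = panel.alt_freq(int(s))
            cols = []
            for r in records:
                gt = f"{int(r.gt[j, 0])}|{int(r.gt[j, 1])}"
                gp = ",".join(f"{x:.6f}" for x in r.gp[j])
                cols.append(f"{gt}:{r.ds[j]:.6f}:{gp}")
            fh.write(
                f"{site.chrom}\t{site.pos_bp + 1}\t.\t{site.ref}\t{site.alt}\t.\t"
                f"PASS\tRAF={raf:.6f}\tGT:DS:GP\t" + "\t".join(cols) + "\n"
            )


def read_imputed_vcf(path):
    """Returns (keys, samples, ds, gt, gp, raf): ds (n_sample, n_site),
    gt (n_sample, n_site, 2), gp (n_sample, n_site, 3), raf (n_site,)."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    keys, ds_rows, gt_rows, gp_rows, rafs = [], [], [], [], []
    for v in vcf:
        keys.append(site_key(v.CHROM, v.POS - 1, v.REF, v.ALT[0]))
        ds_rows.append(np.asarray(v.format("DS"), dtype=np.float64)[:, 0])
        gp_rows.append(np.asarray(v.format("GP"), dtype=np.float64))
        gt_rows.append([[g[0], g[1]] for g in v.genotypes])
        rafs.append(float(v.INFO.get("RAF")))
    if not keys:
        z = np.zeros
        return keys, samples, z((len(samples), 0)), z((len(samples), 0, 2)), z(
            (len(samples), 0, 3)
        ), z(0)
    ds = np.stack(ds_rows, axis=1)
    gt = np.asarray(gt_rows, dtype=np.int8).transpose(1, 0, 2)
    gp = np.stack(gp_rows, axis=1)
    return keys, samples, ds, gt, gp, np.asarray(rafs)
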