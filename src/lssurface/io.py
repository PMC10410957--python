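"""Readers for plain-text allele matrices and phased VCF."""

from __future__ import annotations

import numpy as np

from .model import BIALLELIC, NUCLEOTIDES, AlleleMatrix, GenotypeSequence, Haplotype

__all__ = ["read_matrix", "read_haplotype", "read_genotypes", "read_vcf"]


def _load_table(path) -> np.ndarray:
    with open(path) as fh:
        first = fh.readline()
    delim = "," if "," in first else None
    return np.atleast_2d(np.loadtxt(path, dtype=np.int64, delimiter=delim))


def read_matrix(path, alphabet=BIALLELIC) -> AlleleMatrix:
    """Whitespace- or comma-separated L x N integer matrix, one row per site."""
    return AlleleMatrix(_load_table(path), alphabet=alphabet)


def read_haplotype(path) -> Haplotype:
    """Focal haplotype from a one-column (or one-row) text file."""
    arr = _load_table(path)
    return Haplotype(arr.reshape(-1))


def read_genotypes(path) -> GenotypeSequence:
    """Unphased diplotype from an L x 2 text file of allele pairs."""
    arr = _load_table(path)
    if arr.shape[1] != 2:
        raise ValueError("genotype file must have exactly two columns")
    return GenotypeSequence(arr)


def read_vcf(path, focal_sample: str, alphabet=BIALLELIC):
    """Split a phased VCF into a template panel and a focal sample.

    Returns ``(panel, focal_haplotypes)`` where ``panel`` stacks the two
    phased haplotypes of every non-focal sample as columns and
    ``focal_haplotypes`` is the (h1, h2) pair of the designated sample.
    Multiallelic records are rejected unless the nucleotide alphabet is
    requested.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if focal_sample not in samples:
        raise ValueError(f"sample {focal_sample!r} not present in VCF")
    fi = samples.index(focal_sample)
    nucleotide = tuple(alphabet) == tuple(NUCLEOTIDES)
    code = {b: i for i, b in enumerate("ACGT")}
    rows, focal_rows, positions = [], [], []
    for rec in vcf:
        if len(rec.ALT) > 1 and not nucleotide:
            raise ValueError(
                f"multiallelic record at {rec.CHROM}:{rec.POS}; use the nucleotide alphabet"
            )
        gts = rec.genotypes  # [a0, a1, phased] per sample
        for s, gt in enumerate(gts):
            if len(gt) < 3 or not gt[2]:
                raise ValueError(f"unphased genotype at {rec.CHROM}:{rec.POS}")
        if nucleotide:
            alleles = [rec.REF.upper()] + [a.upper() for a in rec.ALT]
            conv = [code[a] for a in alleles]
            row = [conv[gt[j]] for s, gt in enumerate(gts) if s != fi for j in (0, 1)]
            frow = [conv[gts[fi][0]], conv[gts[fi][1]]]
        else:
            row = [gt[j] for s, gt in enumerate(gts) if s != fi for j in (0, 1)]
            frow = [gts[fi][0], gts[fi][1]]
        rows.append(row)
        focal_rows.append(frow)
        positions.append(rec.POS)
    if not rows:
        raise ValueError("VCF contains no usable records")
    panel = AlleleMatrix(
        np.asarray(rows, dtype=np.int64),
        alphabet=tuple(alphabet),
        positions=np.asarray(positions, dtype=float),
    )
    focal = np.asarray(focal_rows, dtype=np.int64)
    return panel, (Haplotype(focal[:, 0]), Haplotype(focal[:, 1]))
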