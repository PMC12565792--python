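"""Genotype data model and VCF / table I/O.

The central container is :class:`GenotypeMatrix`: a samples x SNPs diploid
dosage matrix (count of alternate alleles, 0/1/2, with ``MISSING`` for
uncalled genotypes) plus per-SNP chromosome/position/allele metadata.  All
downstream stages — filtering, per-chromosome PCA, karyotyping, association
and LD profiling — operate on this object.

Coordinates are 1-based (VCF convention); every sliding window elsewhere in
the package is half-open ``[start, start + W)`` on these 1-based positions.
Phased and unphased genotypes are treated identically: only the allele
counts matter.  A half-missing genotype (e.g. ``./1``) is conservatively
coded as MISSING rather than a fractional dosage.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel for an uncalled genotype in the dosage matrix.
MISSING: int = -1


class EmptyInputError(ValueError):
    """Raised when an input yields no usable biallelic SNP records."""


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with per-SNP metadata.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers (rows of ``dosage``).
    chrom
        Per-SNP chromosome name, one entry per dosage column.
    pos
        Per-SNP 1-based position; strictly increasing within a chromosome.
    ref, alt
        Per-SNP reference / alternate allele (single bases).
    dosage
        ``(n_samples, n_snps)`` integer array with entries in
        ``{0, 1, 2, MISSING}``.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(str(c), None)
        return list(seen)

    def snp_mask(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the SNP columns selected by ``mask``."""
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            dosage=self.dosage[:, mask],
        )

    def sample_mask(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the sample rows selected by ``mask``."""
        ids = [s for s, keep in zip(self.sample_ids, mask) if keep]
        return GenotypeMatrix(
            sample_ids=ids,
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            dosage=self.dosage[np.asarray(mask, dtype=bool), :],
        )

    def subset_chrom(self, chrom: str) -> "GenotypeMatrix":
        return self.snp_mask(self.chrom == chrom)

    def validate(self) -> None:
        """Check the container invariants; raise ``ValueError`` on violation."""
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        n, m = self.dosage.shape
        if n != len(self.sample_ids):
            raise ValueError("dosage row count does not match sample_ids")
        for name, arr in (("chrom", self.chrom), ("pos", self.pos),
                          ("ref", self.ref), ("alt", self.alt)):
            if len(arr) != m:
                raise ValueError(f"{name} length does not match dosage columns")
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosage entries outside {0, 1, 2, MISSING}")
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")


@dataclass
class ChromosomeTable:
    """Chromosome name -> length (bp) lookup."""

    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"non-positive length for chromosome {name}")

    def __getitem__(self, name: str) -> int:
        try:
            return self.lengths[name]
        except KeyError:
            raise KeyError(
                f"no length known for chromosome {name!r}; provide a "
                "chromosome table or VCF contig headers"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.lengths


def read_chrom_table(path: str) -> ChromosomeTable:
    """Read a two-column (name, length) TSV into a :class:`ChromosomeTable`."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed chromosome table line: {line!r}")
            name, length = fields[0], int(fields[1])
            if name in lengths:
                raise ValueError(f"duplicate chromosome name {name!r}")
            lengths[name] = length
    return ChromosomeTable(lengths)


def _parse_region(region: str) -> tuple[str, int | None, int | None]:
    if ":" not in region:
        return region, None, None
    chrom, span = region.split(":", 1)
    start, end = span.split("-", 1)
    return chrom, int(start), int(end)


def read_vcf(path: str, region: str | None = None
             ) -> tuple[GenotypeMatrix, ChromosomeTable]:
    """Read diploid GT calls from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are skipped (count logged).  ``./.`` and
    half-missing genotypes become :data:`MISSING`.  Contig header lines with
    lengths populate the returned :class:`ChromosomeTable` (empty if the
    header carries none).

    Parameters
    ----------
    path
        VCF or VCF.gz file with GT fields.
    region
        Optional ``chrom`` or ``chrom:start-end`` restriction (1-based,
        inclusive), applied while streaming — no index required.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except OSError as exc:  # pragma: no cover - exercised via bad path test
        raise OSError(f"cannot read VCF {path!r}: {exc}") from exc

    want_chrom = want_start = want_end = None
    if region is not None:
        want_chrom, want_start, want_end = _parse_region(region)

    samples = list(vcf.samples)
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if want_chrom is not None:
            if var.CHROM != want_chrom:
                continue
            if want_start is not None and not (want_start <= var.POS <= want_end):
                continue
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        gts = np.asarray(var.genotypes, dtype=np.int64)[:, :2]
        d = gts.sum(axis=1).astype(np.int8)
        d[(gts < 0).any(axis=1)] = MISSING
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(d)

    try:
        seqlens = vcf.seqlens
    except AttributeError:       # contig lines without length attributes
        seqlens = []
    table = ChromosomeTable({
        name: int(length)
        for name, length in zip(vcf.seqnames, seqlens or [])
        if length
    })
    vcf.close()

    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    if not rows:
        raise EmptyInputError(f"no biallelic SNPs found in {path!r}")

    gm = GenotypeMatrix(
        sample_ids=samples,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        dosage=np.column_stack(rows) if rows else np.empty((len(samples), 0)),
    )
    return gm, table


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str,
              chrom_table: ChromosomeTable | None = None) -> None:
    """Write a GenotypeMatrix as a minimal GT-only VCF (``.gz`` → gzip).

    Round-trip contract: ``read_vcf(write_vcf(gm))`` reproduces
    ``sample_ids``, ``chrom``, ``pos`` and ``dosage`` exactly.
    """
    if gm.n_samples == 0:
        raise ValueError("refusing to write a VCF with zero samples")
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in gm.chromosomes():
            if chrom_table is not None and c in chrom_table:
                fh.write(f"##contig=<ID={c},length={chrom_table[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for j in range(gm.n_snps):
            gts = "\t".join(_GT_CODE[int(d)] for d in gm.dosage[:, j])
            fh.write(f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t"
                     f"{gm.alt[j]}\t.\t.\t.\tGT\t{gts}\n")
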