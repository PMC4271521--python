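"""Input sources for the window scan and small-table readers.

A *site source* iterates ``(scaffold, position, allele_codes)`` records
sorted by scaffold and position, where ``allele_codes`` is an int8 array
over haplotypes (0..3 for A,C,G,T and -1 for missing), and exposes

* ``haplotype_names`` -- one name per haplotype row,
* ``hap_individual``  -- the individual index of each haplotype (used to
  exclude within-individual pairs from pi and to count genotype calls),
* ``scaffold_lengths`` -- mapping scaffold -> length in bp where known.

:class:`VcfSource` expands diploid genotypes into haplotypes (phasing is
irrelevant to frequency- and pairwise-difference-based statistics);
invariant records of an all-sites VCF are kept so that per-site pi and
d_XY denominators count every called site.  :class:`FastaSource` treats
one alignment as a single scaffold of haploid sequences.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .core import MISSING

__all__ = [
    "read_population_map",
    "read_chromosome_map",
    "VcfSource",
    "FastaSource",
    "MatrixSource",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _read_two_columns(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            out[parts[0]] = parts[1]
    return out


def read_population_map(path) -> dict[str, str]:
    """Read a two-column sample -> group file (groups P1, P2, P3, O)."""
    mapping = _read_two_columns(path)
    bad = {g for g in mapping.values() if g not in ("P1", "P2", "P3", "O")}
    if bad:
        raise ValueError(f"{path}: unknown population labels {sorted(bad)}")
    return mapping


def read_chromosome_map(path) -> dict[str, str]:
    """Read a two-column scaffold -> chromosome file."""
    return _read_two_columns(path)


class MatrixSource:
    """In-memory site source over one or more scaffolds.

    ``scaffolds`` is a list of ``(name, length, positions, matrix)``
    tuples with ``matrix`` of shape (n_haplotypes, n_sites).
    """

    def __init__(self, scaffolds, haplotype_names, hap_individual=None):
        self.scaffolds = scaffolds
        self.haplotype_names = list(haplotype_names)
        n = len(self.haplotype_names)
        self.hap_individual = (
            np.arange(n) if hap_individual is None else np.asarray(hap_individual)
        )
        self.scaffold_lengths = {name: length for name, length, _, _ in scaffolds}

    def __iter__(self):
        for name, _length, positions, matrix in self.scaffolds:
            matrix = np.asarray(matrix, dtype=np.int8)
            for j, pos in enumerate(positions):
                yield name, int(pos), matrix[:, j]


class VcfSource:
    """Stream SNP and invariant records of a VCF as haplotype site columns.

    Records whose REF or ALT alleles are not single nucleotides are
    skipped (indels, spanning deletions, symbolic alleles).  Each diploid
    sample contributes two haplotype rows named ``<sample>_1`` and
    ``<sample>_2``; a half-missing genotype marks only the missing
    haplotype as uncalled.
    """

    def __init__(self, path):
        import cyvcf2

        self.path = str(path)
        self._vcf = cyvcf2.VCF(self.path)
        self.samples = list(self._vcf.samples)
        if not self.samples:
            raise ValueError(f"{path}: VCF contains no samples")
        self.haplotype_names = [f"{s}_{k}" for s in self.samples for k in (1, 2)]
        self.hap_individual = np.repeat(np.arange(len(self.samples)), 2)
        try:
            self.scaffold_lengths = dict(zip(self._vcf.seqnames, self._vcf.seqlens))
        except Exception:  # header without contig lengths
            self.scaffold_lengths = {}

    def __iter__(self):
        n_hap = 2 * len(self.samples)
        for variant in self._vcf:
            ref = variant.REF.upper()
            alts = [a.upper() for a in variant.ALT]
            if ref not in _CODE or any(a not in _CODE for a in alts):
                continue
            allele_codes = np.array(
                [_CODE[ref]] + [_CODE[a] for a in alts] + [MISSING], dtype=np.int8
            )
            gts = np.asarray(variant.genotype.array())[:, :2].reshape(n_hap)
            col = allele_codes[np.where(gts < 0, len(allele_codes) - 1, gts)]
            yield variant.CHROM, variant.POS - 1, col


class FastaSource:
    """A FASTA alignment of haploid sequences as a single-scaffold source.

    All sequences must have equal length; characters outside ACGT
    (case-insensitive) are treated as missing.  ``individuals`` may map
    each record id to an individual label; by default every sequence is
    its own individual.
    """

    def __init__(self, path, scaffold: str | None = None, individuals=None):
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"{path}: empty FASTA alignment")
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            raise ValueError(f"{path}: sequences are not aligned (unequal lengths)")
        (length,) = lengths
        self.haplotype_names = [r.id for r in records]
        if individuals is None:
            self.hap_individual = np.arange(len(records))
        else:
            labels = [individuals[r.id] for r in records]
            uniq = {lab: i for i, lab in enumerate(dict.fromkeys(labels))}
            self.hap_individual = np.array([uniq[lab] for lab in labels])
        scaffold = scaffold or Path(str(path)).stem
        from .core import encode_nucleotides

        matrix = encode_nucleotides(
            np.array([list(str(r.seq).upper()) for r in records])
        )
        self._inner = MatrixSource(
            [(scaffold, length, np.arange(length), matrix)],
            self.haplotype_names,
            self.hap_individual,
        )
        self.scaffold_lengths = self._inner.scaffold_lengths

    def __iter__(self):
        return iter(self._inner)
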