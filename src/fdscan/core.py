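"""Four-taxon site-pattern statistics.

Given population samples P1, P2, P3 and an outgroup O with the species
relationship (((P1,P2),P3),O), biallelic sites are polarized against the
outgroup and each segregating site is weighted by how well it fits the
ABBA pattern (derived allele shared by P2 and P3) or the BABA pattern
(derived allele shared by P1 and P3).  With ``p1..p4`` the derived-allele
frequencies in the four groups, the weights are

    cABBA = (1 - p1) * p2 * p3 * (1 - p4)
    cBABA = p1 * (1 - p2) * p3 * (1 - p4)

Patterson's D is the normalized difference of the summed weights; the
numerator alone is the quantity S.  Three estimators of the admixture
proportion f divide the observed S by the S expected under complete
introgression from P3 into P2:

* ``f_g``   -- the denominator splits the P3 sample into two halves
  (P3a, P3b) standing in for recipient and donor;
* ``f_hom`` -- assumes complete homogenization of allele frequencies,
  substituting p3 for p2 in the denominator;
* ``f_d``   -- picks, per site, the donor P_D as whichever of P2/P3 has
  the higher derived-allele frequency, which caps the estimate at 1 on
  windows with an ABBA excess.

All statistics carry an explicit missing state (``value is None``) when
their denominator is zero (or non-positive for the f ratios) rather than
propagating NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GROUP_NAMES",
    "MISSING",
    "PatternWeights",
    "PolarizedSite",
    "PolarizedSiteTable",
    "StatisticResult",
    "encode_nucleotides",
    "polarize_sites",
    "pattern_weights",
    "s_statistic",
    "d_statistic",
    "f_g",
    "f_hom",
    "f_d",
    "all_statistics",
]

GROUP_NAMES = ("P1", "P2", "P3", "O")

#: integer code for a missing allele call in genotype matrices
MISSING = -1

_NUCLEOTIDES = "ACGT"
_CODE = {c: i for i, c in enumerate(_NUCLEOTIDES)}


def encode_nucleotides(matrix) -> np.ndarray:
    """Return an int8 matrix with A,C,G,T -> 0..3 and anything else -> -1.

    Accepts an integer array (returned as int8 unchanged, values outside
    0..3 mapped to -1) or an array/nested sequence of single-character
    strings or bytes.
    """
    arr = np.asarray(matrix)
    if arr.dtype.kind in "iu":
        out = arr.astype(np.int8, copy=True)
        out[(out < 0) | (out > 3)] = MISSING
        return out
    if arr.dtype.kind == "S":
        arr = arr.astype("U1")
    if arr.dtype.kind != "U":
        raise TypeError(f"cannot encode allele matrix of dtype {arr.dtype}")
    out = np.full(arr.shape, MISSING, dtype=np.int8)
    up = np.char.upper(arr)
    for nuc, code in _CODE.items():
        out[up == nuc] = code
    return out


@dataclass(frozen=True)
class PatternWeights:
    """Per-site fit to the ABBA and BABA patterns, each in [0, 1]."""

    cabba: float
    cbaba: float


@dataclass(frozen=True)
class PolarizedSite:
    """A biallelic site polarized to ancestral/derived states.

    ``p1..p4`` are derived-allele frequencies in P1, P2, P3 and the
    outgroup; ``called1..called4`` count the non-missing haplotypes the
    frequencies were computed from (each is at least 1 by construction).
    ``p3a``/``p3b`` are the derived frequencies in the two interleaved
    halves of the P3 sample used by :func:`f_g`.
    """

    position: int
    p1: float
    p2: float
    p3: float
    p4: float
    called1: int = 1
    called2: int = 1
    called3: int = 1
    called4: int = 1
    p3a: float | None = None
    p3b: float | None = None


@dataclass(frozen=True)
class StatisticResult:
    """A ratio statistic with its components.

    ``value`` is ``None`` exactly when the denominator is zero (D) or
    non-positive (the f estimators).
    """

    value: float | None
    numerator: float
    denominator: float
    n_sites_used: int

    def __float__(self) -> float:
        return float("nan") if self.value is None else self.value


class PolarizedSiteTable:
    """Array-backed collection of :class:`PolarizedSite` records.

    Columns follow the group order P1, P2, P3, O.  Indexing returns a
    :class:`PolarizedSite`; the frequency arrays are exposed directly for
    vectorized computation.
    """

    __slots__ = ("positions", "freqs", "called", "p3a", "p3b")

    def __init__(self, positions, freqs, called, p3a=None, p3b=None):
        self.positions = np.asarray(positions, dtype=np.int64)
        self.freqs = np.asarray(freqs, dtype=np.float64)
        self.called = np.asarray(called, dtype=np.int64)
        n = len(self.positions)
        if self.freqs.shape != (n, 4) or self.called.shape != (n, 4):
            raise ValueError("freqs and called must have shape (n_sites, 4)")
        if np.any((self.freqs < 0) | (self.freqs > 1)):
            raise ValueError("derived-allele frequencies must lie in [0, 1]")
        if n and np.any(self.called < 1):
            raise ValueError("every group must have >= 1 called haplotype")
        self.p3a = None if p3a is None else np.asarray(p3a, dtype=np.float64)
        self.p3b = None if p3b is None else np.asarray(p3b, dtype=np.float64)

    @classmethod
    def from_sites(cls, sites: Iterable[PolarizedSite]) -> "PolarizedSiteTable":
        sites = list(sites)
        positions = [s.position for s in sites]
        freqs = [(s.p1, s.p2, s.p3, s.p4) for s in sites]
        called = [(s.called1, s.called2, s.called3, s.called4) for s in sites]
        have_split = all(s.p3a is not None and s.p3b is not None for s in sites)
        p3a = [s.p3a for s in sites] if have_split and sites else None
        p3b = [s.p3b for s in sites] if have_split and sites else None
        return cls(
            np.asarray(positions, dtype=np.int64),
            np.asarray(freqs, dtype=np.float64).reshape(len(sites), 4),
            np.asarray(called, dtype=np.int64).reshape(len(sites), 4),
            p3a,
            p3b,
        )

    def __len__(self) -> int:
        return len(self.positions)

    def __getitem__(self, i: int) -> PolarizedSite:
        return PolarizedSite(
            position=int(self.positions[i]),
            p1=float(self.freqs[i, 0]),
            p2=float(self.freqs[i, 1]),
            p3=float(self.freqs[i, 2]),
            p4=float(self.freqs[i, 3]),
            called1=int(self.called[i, 0]),
            called2=int(self.called[i, 1]),
            called3=int(self.called[i, 2]),
            called4=int(self.called[i, 3]),
            p3a=None if self.p3a is None else float(self.p3a[i]),
            p3b=None if self.p3b is None else float(self.p3b[i]),
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


def _group_rows(
    group_map: Mapping[str, str] | Sequence[str],
    sample_names: Sequence[str] | None,
    n_rows: int,
) -> dict[str, np.ndarray]:
    """Resolve the haplotype rows belonging to each of the four groups."""
    if isinstance(group_map, Mapping):
        if sample_names is None:
            sample_names = [str(i) for i in range(n_rows)]
        if len(sample_names) != n_rows:
            raise ValueError("sample_names length does not match matrix rows")
        unknown = set(group_map) - set(sample_names)
        if unknown:
            raise ValueError(f"group map names unknown samples: {sorted(unknown)}")
        labels = [group_map.get(name) for name in sample_names]
    else:
        labels = list(group_map)
        if len(labels) != n_rows:
            raise ValueError("group label sequence length does not match matrix rows")
    bad = {g for g in labels if g is not None and g not in GROUP_NAMES}
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}; expected {GROUP_NAMES}")
    rows = {
        g: np.array([i for i, lab in enumerate(labels) if lab == g], dtype=np.intp)
        for g in GROUP_NAMES
    }
    empty = [g for g, r in rows.items() if r.size == 0]
    if empty:
        raise ValueError(f"groups with no assigned samples: {empty}")
    return rows


def _interleaved_split(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Even sample-indices form the (possibly larger) first half; a
    # contiguous first/second-half split can make the f_G denominator
    # degenerate whenever derived alleles are clustered by sample order.
    return rows[0::2], rows[1::2]


def polarize_sites(
    genotypes,
    group_map: Mapping[str, str] | Sequence[str],
    sample_names: Sequence[str] | None = None,
    positions: Sequence[int] | None = None,
    *,
    outgroup_derived_freq: bool = True,
    p3_split_rng: np.random.Generator | None = None,
) -> PolarizedSiteTable:
    """Polarize biallelic sites of a haplotype-by-site allele matrix.

    A site is retained iff it is biallelic across all called haplotypes
    (of assigned samples) and every one of the four groups has at least
    one called haplotype there.  The ancestral allele is the allele fixed
    among called outgroup haplotypes; if the outgroup is polymorphic, the
    most common allele over all called haplotypes is taken as ancestral
    (ties broken towards the alphabetically first nucleotide).

    Parameters
    ----------
    genotypes
        ``(n_haplotypes, n_sites)`` allele matrix; nucleotide characters
        or integer codes 0..3, with anything else treated as missing.
    group_map
        Either a mapping sample name -> group (requires ``sample_names``)
        or a per-row sequence of group labels (``None`` rows are ignored).
    positions
        Site coordinates; defaults to 0..n_sites-1.
    outgroup_derived_freq
        Keep the outgroup derived-allele frequency p4 as observed
        (nonzero when the outgroup is polymorphic).  When False, p4 is
        forced to 0 after polarization.
    p3_split_rng
        If given, the P3 sample is split randomly (seeded by the caller)
        for the ``f_g`` subgroups instead of the default deterministic
        interleaved odd/even split.
    """
    M = encode_nucleotides(genotypes)
    if M.ndim != 2:
        raise ValueError("genotype matrix must be 2-dimensional")
    n_hap, n_sites = M.shape
    rows = _group_rows(group_map, sample_names, n_hap)
    if positions is None:
        positions = np.arange(n_sites, dtype=np.int64)
    else:
        positions = np.asarray(positions, dtype=np.int64)
        if positions.shape != (n_sites,):
            raise ValueError("positions length does not match matrix columns")
    if n_sites == 0:
        return PolarizedSiteTable(
            np.empty(0, np.int64), np.empty((0, 4)), np.empty((0, 4), np.int64)
        )

    assigned = np.concatenate([rows[g] for g in GROUP_NAMES])
    rows3 = rows["P3"]
    if p3_split_rng is not None:
        perm = rows3[p3_split_rng.permutation(rows3.size)]
        rows3a, rows3b = _interleaved_split(perm)
    else:
        rows3a, rows3b = _interleaved_split(rows3)

    subsets = [rows[g] for g in GROUP_NAMES] + [assigned, rows3a, rows3b]
    # counts[k, a, s]: copies of allele a at site s within subset k
    counts = np.empty((len(subsets), 4, n_sites), dtype=np.int64)
    for a in range(4):
        hit = M == a
        for k, sub in enumerate(subsets):
            counts[k, a] = hit[sub].sum(axis=0)

    total = counts[4]  # over all assigned haplotypes
    present = total > 0
    biallelic = present.sum(axis=0) == 2
    called = counts[:4].sum(axis=1)  # (group, site)
    keep = biallelic & (called > 0).all(axis=0)
    if not keep.any():
        return PolarizedSiteTable(
            np.empty(0, np.int64), np.empty((0, 4)), np.empty((0, 4), np.int64)
        )

    counts = counts[:, :, keep]
    total = total[:, keep]
    called = called[:, keep]
    positions = positions[keep]
    present = total > 0
    # the two alleles of each biallelic site, low and high code
    allele_lo = present.argmax(axis=0)
    allele_hi = 3 - (present[::-1].argmax(axis=0))

    og = counts[3]
    og_called = og.sum(axis=0)
    og_lo = og[allele_lo, np.arange(og.shape[1])]
    og_hi = og[allele_hi, np.arange(og.shape[1])]
    og_fixed_lo = (og_lo == og_called) & (og_called > 0)
    og_fixed_hi = (og_hi == og_called) & (og_called > 0)
    majority = np.where(
        total[allele_lo, np.arange(total.shape[1])]
        >= total[allele_hi, np.arange(total.shape[1])],
        allele_lo,
        allele_hi,
    )
    ancestral = np.where(og_fixed_lo, allele_lo, np.where(og_fixed_hi, allele_hi, majority))
    derived = np.where(ancestral == allele_lo, allele_hi, allele_lo)

    site_idx = np.arange(derived.size)
    freqs = np.empty((derived.size, 4))
    for g in range(4):
        freqs[:, g] = counts[g][derived, site_idx] / called[g]
    if not outgroup_derived_freq:
        freqs[:, 3] = 0.0

    def _sub_freq(k: int) -> np.ndarray:
        sub_counts = counts[k]
        sub_called = sub_counts.sum(axis=0)
        out = np.empty(derived.size)
        ok = sub_called > 0
        out[ok] = sub_counts[derived[ok], site_idx[ok]] / sub_called[ok]
        # a subgroup with no calls at a site falls back to the full P3 frequency
        out[~ok] = freqs[~ok, 2]
        return out

    p3a = _sub_freq(5)
    p3b = _sub_freq(6)
    return PolarizedSiteTable(positions, freqs, called.T.copy(), p3a, p3b)


def _as_table(sites) -> PolarizedSiteTable:
    if isinstance(sites, PolarizedSiteTable):
        return sites
    return PolarizedSiteTable.from_sites(sites)


def _weights(p1, p2, p3, p4):
    cabba = (1.0 - p1) * p2 * p3 * (1.0 - p4)
    cbaba = p1 * (1.0 - p2) * p3 * (1.0 - p4)
    return cabba, cbaba


def pattern_weights(site: PolarizedSite) -> PatternWeights:
    """ABBA/BABA weights of a single polarized site."""
    cabba, cbaba = _weights(site.p1, site.p2, site.p3, site.p4)
    return PatternWeights(float(cabba), float(cbaba))


def s_statistic(weights) -> float:
    """Difference between summed ABBA and BABA weights (the S quantity)."""
    if isinstance(weights, PatternWeights):
        weights = [weights]
    weights = list(weights)
    if not weights:
        return 0.0
    cabba = np.array([w.cabba if isinstance(w, PatternWeights) else w[0] for w in weights])
    cbaba = np.array([w.cbaba if isinstance(w, PatternWeights) else w[1] for w in weights])
    return float(cabba.sum() - cbaba.sum())


def _ratio(num: float, den: float, used: int, *, allow_negative_den: bool) -> StatisticResult:
    missing = den == 0.0 if allow_negative_den else den <= 0.0
    value = None if missing else num / den
    return StatisticResult(value, float(num), float(den), int(used))


def d_statistic(sites) -> StatisticResult:
    """Patterson's D over a collection of polarized sites.

    ``value`` is (sum cABBA - sum cBABA) / (sum cABBA + sum cBABA),
    missing when no site carries pattern weight.  Exchanging the P1 and
    P2 frequency columns negates D exactly.
    """
    t = _as_table(sites)
    cabba, cbaba = _weights(t.freqs[:, 0], t.freqs[:, 1], t.freqs[:, 2], t.freqs[:, 3])
    num = float(cabba.sum() - cbaba.sum())
    den = float(cabba.sum() + cbaba.sum())
    used = int(np.count_nonzero(cabba + cbaba))
    return _ratio(num, den, used, allow_negative_den=True)


def _s_numerator(t: PolarizedSiteTable) -> float:
    cabba, cbaba = _weights(t.freqs[:, 0], t.freqs[:, 1], t.freqs[:, 2], t.freqs[:, 3])
    return float(cabba.sum() - cbaba.sum())


def f_hom(sites) -> StatisticResult:
    """f estimator assuming complete homogenization of P2/P3 frequencies.

    The denominator substitutes p3 for p2: S(P1,P3,P3,O).  Missing when
    the denominator is not positive.
    """
    t = _as_table(sites)
    p1, p3, p4 = t.freqs[:, 0], t.freqs[:, 2], t.freqs[:, 3]
    da, db = _weights(p1, p3, p3, p4)
    num = _s_numerator(t)
    den = float(da.sum() - db.sum())
    used = int(np.count_nonzero(da + db))
    return _ratio(num, den, used, allow_negative_den=False)


def f_g(sites, p3a=None, p3b=None) -> StatisticResult:
    """f estimator with a split P3 sample (the original genome-wide form).

    The denominator is S(P1,P3a,P3b,O) with the P3 haplotypes divided by
    the deterministic interleaved odd/even rule (the subgroup built from
    even sample indices takes the extra haplotype when the count is odd).
    The estimate may exceed 1 when derived frequencies happen to be
    higher in one half than the other; missing when the denominator is
    not positive.
    """
    t = _as_table(sites)
    if p3a is None:
        p3a = t.p3a
    if p3b is None:
        p3b = t.p3b
    if p3a is None or p3b is None:
        raise ValueError("f_g requires P3 subgroup frequencies (p3a, p3b)")
    p3a = np.asarray(p3a, dtype=np.float64)
    p3b = np.asarray(p3b, dtype=np.float64)
    p1, p4 = t.freqs[:, 0], t.freqs[:, 3]
    da, db = _weights(p1, p3a, p3b, p4)
    num = _s_numerator(t)
    den = float(da.sum() - db.sum())
    used = int(np.count_nonzero(da + db))
    return _ratio(num, den, used, allow_negative_den=False)


def f_d(sites) -> StatisticResult:
    """Dynamic f estimator with a per-site donor population.

    At each site the donor frequency pD = max(p2, p3) replaces both p2
    and p3 in the denominator weights (P3 is the donor on ties, which
    yields the identical term).  On windows with an ABBA excess (D >= 0)
    the estimate lies in [0, 1].  Missing when the denominator is not
    positive.
    """
    t = _as_table(sites)
    p1, p2, p3, p4 = (t.freqs[:, g] for g in range(4))
    pd = np.maximum(p2, p3)
    da, db = _weights(p1, pd, pd, p4)
    num = _s_numerator(t)
    den = float(da.sum() - db.sum())
    used = int(np.count_nonzero(da + db))
    return _ratio(num, den, used, allow_negative_den=False)


def all_statistics(sites) -> dict[str, StatisticResult | float | int]:
    """Compute S, D and the three f estimators in one pass.

    Returns a dict with keys ``S`` (float), ``D``, ``fG``, ``fhom``,
    ``fd`` (:class:`StatisticResult`) and ``n_sites`` (int).
    """
    t = _as_table(sites)
    return {
        "S": _s_numerator(t),
        "D": d_statistic(t),
        "fG": f_g(t) if t.p3a is not None else None,
        "fhom": f_hom(t),
        "fd": f_d(t),
        "n_sites": len(t),
    }
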