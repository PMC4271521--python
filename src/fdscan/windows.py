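"""Sliding-window genome scan: window iteration, filters, pi and d_XY.

Windows tile each scaffold independently (never spanning a scaffold
join), use 0-based half-open coordinates internally and are
nonoverlapping by default.  A window is retained when enough of its
sites have genotype calls for at least half of the individuals; on the
retained windows the four-taxon statistics of :mod:`fdscan.core` are
computed together with nucleotide diversity (pi) per population and
absolute divergence (d_XY) per population pair, both as per-site means
over pairs of sequences with missing data excluded pairwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import core
from .core import GROUP_NAMES, MISSING

__all__ = [
    "ScanConfig",
    "GenotypeWindow",
    "WindowStatistics",
    "iterate_windows",
    "window_filter",
    "nucleotide_diversity",
    "dxy",
    "scan",
    "write_window_table",
    "summarize_chromosomes",
    "TABLE_COLUMNS",
]

TABLE_COLUMNS = [
    "scaffold",
    "start",
    "end",
    "sites",
    "sitesUsed",
    "D",
    "fG",
    "fhom",
    "fd",
    "S",
    "pi_P1",
    "pi_P2",
    "pi_P3",
    "dxy_P1P2",
    "dxy_P1P3",
    "dxy_P2P3",
]


@dataclass
class ScanConfig:
    """Scan parameters.

    ``window_size`` and ``step`` are in bp (equal step means
    nonoverlapping windows); ``min_genotyped_sites`` is the minimum
    number of window sites with genotype calls for at least
    ``min_called_fraction`` of the individuals ("at least half" rounds
    up for odd counts).  ``group_map`` assigns samples to P1/P2/P3/O.
    """

    group_map: Mapping[str, str] = field(default_factory=dict)
    window_size: int = 5000
    step: int | None = None
    min_genotyped_sites: int = 3000
    min_called_fraction: float = 0.5
    pi_within_individuals: bool = False
    outgroup_derived_freq: bool = True

    def __post_init__(self) -> None:
        if self.step is None:
            self.step = self.window_size
        if not (0 < self.step <= self.window_size):
            raise ValueError("require 0 < step <= window_size")
        if not (0 < self.min_called_fraction <= 1):
            raise ValueError("require 0 < min_called_fraction <= 1")
        if self.min_genotyped_sites > self.window_size:
            raise ValueError("min_genotyped_sites cannot exceed window_size")


@dataclass
class GenotypeWindow:
    """Genotypes of one window: haplotype-by-site matrix plus metadata."""

    scaffold: str
    start: int
    end: int
    positions: np.ndarray  # (n_sites,), within-scaffold coordinates
    matrix: np.ndarray  # (n_haplotypes, n_sites) int8, -1 = missing
    haplotype_names: list[str]
    hap_individual: np.ndarray  # individual index per haplotype row
    partial: bool = False

    @property
    def n_individuals(self) -> int:
        return int(self.hap_individual.max()) + 1 if self.hap_individual.size else 0

    def sites_with_individual_calls(self, min_fraction: float) -> int:
        """Number of sites fully genotyped in >= min_fraction of individuals."""
        if self.matrix.size == 0:
            return 0
        n_ind = self.n_individuals
        threshold = math.ceil(min_fraction * n_ind)
        called = self.matrix != MISSING
        # an individual counts as called at a site when all its haplotype
        # entries are non-missing (a complete genotype call)
        ind_called = np.ones((n_ind, self.matrix.shape[1]), dtype=bool)
        np.logical_and.at(ind_called, self.hap_individual, called)
        return int(np.count_nonzero(ind_called.sum(axis=0) >= threshold))


@dataclass
class WindowStatistics:
    scaffold: str
    start: int
    end: int
    n_sites_called: int
    n_sites_biallelic: int
    D: float | None
    fG: float | None
    fhom: float | None
    fd: float | None
    S: float
    pi: dict[str, float | None]
    dxy: dict[str, float | None]
    partial: bool = False

    def to_row(self) -> dict:
        row = {
            "scaffold": self.scaffold,
            "start": self.start,
            "end": self.end,
            "sites": self.n_sites_called,
            "sitesUsed": self.n_sites_biallelic,
            "D": self.D,
            "fG": self.fG,
            "fhom": self.fhom,
            "fd": self.fd,
            "S": self.S,
        }
        for g in ("P1", "P2", "P3"):
            row[f"pi_{g}"] = self.pi.get(g)
        for pair in ("P1P2", "P1P3", "P2P3"):
            row[f"dxy_{pair}"] = self.dxy.get(pair)
        return row


class UnsortedInputError(ValueError):
    """Raised when the site stream is not sorted by scaffold and position."""


def iterate_windows(source, config: ScanConfig) -> Iterator[GenotypeWindow]:
    """Yield genotype windows tiling each scaffold of a site source.

    ``source`` must expose ``haplotype_names``, ``hap_individual``,
    ``scaffold_lengths`` (mapping, possibly empty) and iterate
    ``(scaffold, position, allele_codes)`` records sorted by scaffold
    then position.  Scaffolds are tiled from coordinate 0; a trailing
    window shorter than ``window_size`` is emitted flagged as partial.
    Scaffolds without any site records yield no windows.
    """
    hap_names = list(source.haplotype_names)
    hap_ind = np.asarray(source.hap_individual, dtype=np.intp)
    lengths = dict(getattr(source, "scaffold_lengths", {}) or {})

    def _flush(scaffold, positions, columns):
        if not positions:
            return
        pos = np.asarray(positions, dtype=np.int64)
        mat = np.column_stack(columns).astype(np.int8)
        scaffold_len = lengths.get(scaffold, int(pos[-1]) + 1)
        for start in range(0, scaffold_len, config.step):
            end = min(start + config.window_size, scaffold_len)
            if end <= start:
                continue
            lo, hi = np.searchsorted(pos, [start, end])
            yield GenotypeWindow(
                scaffold=scaffold,
                start=start,
                end=end,
                positions=pos[lo:hi],
                matrix=mat[:, lo:hi],
                haplotype_names=hap_names,
                hap_individual=hap_ind,
                partial=end - start < config.window_size,
            )

    current = None
    seen: set[str] = set()
    last_pos = -1
    positions: list[int] = []
    columns: list[np.ndarray] = []
    for scaffold, pos, col in source:
        if scaffold != current:
            yield from _flush(current, positions, columns)
            if scaffold in seen:
                raise UnsortedInputError(
                    f"input not sorted: scaffold {scaffold!r} reappears at position {pos}"
                )
            if current is not None:
                seen.add(current)
            current, last_pos = scaffold, -1
            positions, columns = [], []
        if pos < last_pos:
            raise UnsortedInputError(
                f"input not sorted: {scaffold}:{pos} after {scaffold}:{last_pos}"
            )
        last_pos = pos
        positions.append(pos)
        columns.append(col)
    yield from _flush(current, positions, columns)


def window_filter(window: GenotypeWindow, config: ScanConfig) -> bool:
    """Keep a window iff enough sites are genotyped in enough individuals."""
    if config.min_genotyped_sites == 0:
        return True
    qualifying = window.sites_with_individual_calls(config.min_called_fraction)
    return qualifying >= config.min_genotyped_sites


def _pair_stats(a: np.ndarray, b: np.ndarray, extra_called: int) -> tuple[int, int]:
    joint = (a != MISSING) & (b != MISSING)
    diffs = int(np.count_nonzero((a != b) & joint))
    return diffs, int(joint.sum()) + extra_called


def _mean_pairwise(
    pairs: Iterable[tuple[np.ndarray, np.ndarray]], extra_called: int
) -> float | None:
    values = []
    for a, b in pairs:
        diffs, joint = _pair_stats(a, b, extra_called)
        if joint > 0:
            values.append(diffs / joint)
    return float(np.mean(values)) if values else None


def nucleotide_diversity(
    haplotypes,
    *,
    n_invariant: int = 0,
    individuals=None,
    within_individuals: bool = False,
) -> float | None:
    """Per-site nucleotide diversity pi of one population sample.

    Mean over haplotype pairs of (differences / jointly called sites);
    every pair contributes equally and pairs with no jointly called site
    are excluded.  ``n_invariant`` counts additional monomorphic, fully
    called sites not present in the matrix (used when only variant
    columns are stored).  By default pairs of haplotypes from the same
    individual are excluded; pass ``within_individuals=True`` to include
    them.  Returns ``None`` with fewer than two haplotypes or no valid
    pair.
    """
    h = core.encode_nucleotides(haplotypes)
    n = h.shape[0]
    if n < 2:
        return None
    ind = np.arange(n) if individuals is None else np.asarray(individuals)
    if not np.any(h == MISSING) and (within_individuals or len(set(ind.tolist())) == n):
        # fast path: no missing data and all pairs eligible
        L = h.shape[1] + n_invariant
        if L == 0:
            return None
        counts = np.stack([(h == a).sum(axis=0) for a in range(4)])
        diff_pairs = (n * n - (counts**2).sum(axis=0)) / 2.0
        n_pairs = n * (n - 1) / 2.0
        return float(diff_pairs.sum() / (n_pairs * L))
    pairs = (
        (h[i], h[j])
        for i, j in combinations(range(n), 2)
        if within_individuals or ind[i] != ind[j]
    )
    return _mean_pairwise(pairs, n_invariant)


def dxy(haplotypes_x, haplotypes_y, *, n_invariant: int = 0) -> float | None:
    """Per-site absolute divergence d_XY between two population samples.

    Mean over all between-population haplotype pairs of
    (differences / jointly called sites), with the same pairwise
    missing-data contract as :func:`nucleotide_diversity`.  Returns
    ``None`` when no pair has a jointly called site.
    """
    hx = core.encode_nucleotides(haplotypes_x)
    hy = core.encode_nucleotides(haplotypes_y)
    if hx.shape[0] == 0 or hy.shape[0] == 0:
        return None
    if not np.any(hx == MISSING) and not np.any(hy == MISSING):
        L = hx.shape[1] + n_invariant
        if L == 0:
            return None
        cx = np.stack([(hx == a).sum(axis=0) for a in range(4)])
        cy = np.stack([(hy == a).sum(axis=0) for a in range(4)])
        nx, ny = hx.shape[0], hy.shape[0]
        diff_pairs = nx * ny - (cx * cy).sum(axis=0)
        return float(diff_pairs.sum() / (nx * ny * L))
    pairs = ((a, b) for a in hx for b in hy)
    return _mean_pairwise(pairs, n_invariant)


def _value(res: core.StatisticResult | None) -> float | None:
    if res is None:
        return None
    return res.value


def window_statistics(
    window: GenotypeWindow,
    config: ScanConfig,
    *,
    n_invariant: int = 0,
) -> WindowStatistics:
    """All per-window statistics on one genotype window."""
    labels = [config.group_map.get(name) for name in window.haplotype_names]
    table = core.polarize_sites(
        window.matrix,
        labels,
        positions=window.positions,
        outgroup_derived_freq=config.outgroup_derived_freq,
    )
    res = core.all_statistics(table)
    rows = {
        g: np.array([i for i, lab in enumerate(labels) if lab == g], dtype=np.intp)
        for g in GROUP_NAMES
    }
    pi = {
        g: nucleotide_diversity(
            window.matrix[rows[g]],
            n_invariant=n_invariant,
            individuals=window.hap_individual[rows[g]],
            within_individuals=config.pi_within_individuals,
        )
        for g in ("P1", "P2", "P3")
    }
    dxy_vals = {
        f"{a}{b}": dxy(window.matrix[rows[a]], window.matrix[rows[b]], n_invariant=n_invariant)
        for a, b in (("P1", "P2"), ("P1", "P3"), ("P2", "P3"))
    }
    return WindowStatistics(
        scaffold=window.scaffold,
        start=window.start,
        end=window.end,
        n_sites_called=window.sites_with_individual_calls(config.min_called_fraction),
        n_sites_biallelic=len(table),
        D=_value(res["D"]),
        fG=_value(res["fG"]),
        fhom=_value(res["fhom"]),
        fd=_value(res["fd"]),
        S=res["S"],
        pi=pi,
        dxy=dxy_vals,
        partial=window.partial,
    )


def scan(source, config: ScanConfig) -> pd.DataFrame:
    """Run the full window scan; one row per retained window.

    Output is deterministic given the input and configuration.  The
    ``start``/``end`` columns are 0-based half-open;
    :func:`write_window_table` converts to 1-based inclusive on disk.
    """
    if not config.group_map:
        raise ValueError("scan requires a group_map assigning samples to P1,P2,P3,O")
    present = set(config.group_map.values())
    missing_groups = [g for g in GROUP_NAMES if g not in present]
    if missing_groups:
        raise ValueError(f"groups with no assigned samples: {missing_groups}")
    rows = []
    for window in iterate_windows(source, config):
        if not window_filter(window, config):
            continue
        rows.append(window_statistics(window, config).to_row())
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_window_table(table: pd.DataFrame, path, *, comments: Mapping | None = None) -> None:
    """Write a window table as TSV: 1-based inclusive coordinates, NA for missing."""
    out = table.copy()
    if "start" in out.columns:
        out["start"] = out["start"] + 1
    with open(path, "w") as fh:
        for key, value in (comments or {}).items():
            fh.write(f"# {key}={value}\n")
        out.to_csv(fh, sep="\t", index=False, na_rep="NA")


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float | None, float | None, int]:
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return None, None, max(n - 2, 0)
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), n - 2


def summarize_chromosomes(
    table: pd.DataFrame, chromosome_map: Mapping[str, str]
) -> tuple[pd.DataFrame, dict]:
    """Per-chromosome variance of D and of f_d (D >= 0 windows), mean pi,
    and the cross-chromosome Pearson correlations of those variances with
    mean diversity (degrees of freedom n - 2).

    Chromosomes with a single window get missing variances; degenerate
    (constant) columns yield missing correlations.
    """
    df = table.copy()
    df["chromosome"] = df["scaffold"].map(dict(chromosome_map))
    df = df.dropna(subset=["chromosome"])
    pi_cols = [c for c in df.columns if c.startswith("pi_")]
    records = []
    for chrom, grp in df.groupby("chromosome", sort=True):
        d = grp["D"].dropna().to_numpy(dtype=float)
        fd = grp.loc[grp["D"] >= 0, "fd"].dropna().to_numpy(dtype=float)
        records.append(
            {
                "chromosome": chrom,
                "n_windows": len(grp),
                "var_D": float(np.var(d, ddof=1)) if len(d) >= 2 else None,
                "var_fd": float(np.var(fd, ddof=1)) if len(fd) >= 2 else None,
                "mean_pi": float(np.nanmean(grp[pi_cols].to_numpy(dtype=float)))
                if pi_cols
                else None,
            }
        )
    summary = pd.DataFrame(records)
    correlations = {}
    if len(summary):
        mean_pi = summary["mean_pi"].to_numpy(dtype=float)
        for col in ("var_D", "var_fd"):
            vals = summary[col].to_numpy(dtype=float)
            r, p, dof = _pearson(vals, mean_pi)
            correlations[f"{col}_vs_mean_pi"] = {"r": r, "p": p, "df": dof}
    return summary, correlations
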