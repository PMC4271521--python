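"""Coalescent simulation of four-taxon sequence windows.

Histories follow the species topology (((P1,P2),P3),O) ("background")
or ((P1,(P2,P3)),O) ("alternate"), with all times in units of 4N
generations and a constant, equal population size.  Genealogies are
sampled with msprime (haploid samples, population size 1/2, so that one
msprime generation equals one 4N-generation unit and a pair of lineages
in a population coalesces at rate 2, matching the classic ``ms``
scaling).  Recombination is parameterized as a per-bp population rate
4Nr, so the total window rate is ``rho * window_length``.  Sequences
acquire finite-site HKY mutations at ``mutation_scale`` substitutions
per site per branch-length unit; recurrent hits can therefore create
multiallelic sites (excluded from pattern statistics) and back
mutations, as in a Seq-Gen treatment of the same genealogies.

An instantaneous unidirectional admixture event on the background
topology moves each recipient-population lineage to the donor with
probability f when tracing ancestry back past the event time (the
``ms -es/-ej`` idiom with retention 1 - f).

Alternate-topology models are parameterized by their two join times:
``t12`` is the P2-P3 join and ``t23`` the join of their ancestor with
P1.  Complete gene flow P3->P2 keeps the background P3 split
(``t23 = t23_background``); complete gene flow P2->P3 routes the merged
lineage through the background P1-P2 split (``t23 = t12_background``);
ancestral structure joins P2 and P3 at the background ``t23`` and
delays the P1 join to ``t_structure > t23``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import msprime
import numpy as np
import pandas as pd
import tskit

from . import core, windows as _windows

__all__ = [
    "AdmixtureEvent",
    "DemographicModel",
    "CombinedModelSpec",
    "CombinedDataset",
    "SimulatedWindow",
    "ModelPair",
    "simulate_window",
    "simulate_windows",
    "simulate_combined",
    "build_estimator_grid",
    "estimator_grid_statistics",
    "model_grid_tables",
    "subsample_models",
    "write_dataset",
    "GRID_TIMES",
    "DIRECTIONS",
]

DIRECTIONS = ("P3->P2", "P2->P3")

#: split-time grid of the model survey (4N-generation units)
GRID_TIMES = tuple(np.round(np.arange(0.2, 2.01, 0.2), 10))

_NUC = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class AdmixtureEvent:
    """Instantaneous unidirectional admixture at ``time`` (4N units).

    ``proportion`` is f, the probability that each recipient haplotype
    traces its ancestry through the donor at the event time.
    """

    direction: str
    time: float
    proportion: float

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("admixture proportion f must lie in [0, 1]")
        if self.time <= 0:
            raise ValueError("admixture time must be positive")


@dataclass(frozen=True)
class DemographicModel:
    """A four-population history in 4N-generation units.

    For the background topology ``t12``/``t23`` are the P1-P2 and
    (P1P2)-P3 split times; for the alternate topology they are the P2-P3
    join and the subsequent join with P1 (see module docstring).
    """

    t12: float
    t23: float
    t_root: float = 3.0
    topology: str = "background"
    admixture: AdmixtureEvent | None = None
    t_structure: float | None = None
    samples_per_pop: int = 8
    window_length: int = 5000
    rho: float = 0.01
    mutation_scale: float = 0.01
    kappa: float = 1.0  # HKY rate ratio; 1.0 == Seq-Gen's default ts/tv of 0.5 at equal base frequencies
    base_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.topology not in ("background", "alternate"):
            raise ValueError("topology must be 'background' or 'alternate'")
        if not 0 < self.t12 < self.t23 < self.t_root:
            raise ValueError(
                f"require 0 < t12 < t23 < t_root, got {self.t12}, {self.t23}, {self.t_root}"
            )
        if self.admixture is not None:
            if self.topology != "background":
                raise ValueError("admixture events apply to the background topology")
            if not self.admixture.time < self.t12:
                raise ValueError("admixture must predate the P1-P2 split: t_GF < t12")
        if self.t_structure is not None and self.topology != "alternate":
            raise ValueError("t_structure labels an alternate-topology model")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.mutation_scale < 0:
            raise ValueError("mutation_scale must be >= 0")
        if self.samples_per_pop < 1 or self.window_length < 1:
            raise ValueError("samples_per_pop and window_length must be >= 1")
        if abs(sum(self.base_frequencies) - 1.0) > 1e-9:
            raise ValueError("base_frequencies must sum to 1")

    # -- constructors ------------------------------------------------------
    @classmethod
    def background(cls, t12: float, t23: float, **kwargs) -> "DemographicModel":
        return cls(t12=t12, t23=t23, topology="background", **kwargs)

    @classmethod
    def alternate(cls, t_split23: float, t_join1: float, **kwargs) -> "DemographicModel":
        """Alternate topology: P2-P3 join at ``t_split23``, P1 join at ``t_join1``."""
        return cls(t12=t_split23, t23=t_join1, topology="alternate", **kwargs)

    # -- engine ------------------------------------------------------------
    def to_demography(self) -> msprime.Demography:
        dem = msprime.Demography()
        for name in core.GROUP_NAMES:
            dem.add_population(name=name, initial_size=0.5)
        if self.topology == "background":
            if self.admixture is not None and self.admixture.proportion > 0:
                recipient, donor = (
                    ("P2", "P3")
                    if self.admixture.direction == "P3->P2"
                    else ("P3", "P2")
                )
                dem.add_mass_migration(
                    time=self.admixture.time,
                    source=recipient,
                    dest=donor,
                    proportion=self.admixture.proportion,
                )
            dem.add_mass_migration(time=self.t12, source="P2", dest="P1", proportion=1.0)
            dem.add_mass_migration(time=self.t23, source="P3", dest="P1", proportion=1.0)
        else:
            dem.add_mass_migration(time=self.t12, source="P2", dest="P3", proportion=1.0)
            dem.add_mass_migration(time=self.t23, source="P3", dest="P1", proportion=1.0)
        dem.add_mass_migration(time=self.t_root, source="O", dest="P1", proportion=1.0)
        dem.sort_events()
        return dem


def _haplotype_names(samples_per_pop: int) -> list[str]:
    return [f"{g}_{i + 1}" for g in core.GROUP_NAMES for i in range(samples_per_pop)]


@dataclass
class SimulatedWindow:
    """One simulated sequence window.

    ``matrix`` holds nucleotide codes (0..3) at the variant sites only;
    :meth:`full_alignment` expands to all ``window_length`` columns by
    drawing the invariant sites from the model's equilibrium base
    frequencies with the window's own seed.
    """

    matrix: np.ndarray  # (4 * samples_per_pop, n_variant_sites) int8
    positions: np.ndarray  # (n_variant_sites,)
    model: DemographicModel
    label: str = "Background"
    seed: int | None = None

    @property
    def haplotype_names(self) -> list[str]:
        return _haplotype_names(self.model.samples_per_pop)

    @property
    def group_labels(self) -> list[str]:
        return [g for g in core.GROUP_NAMES for _ in range(self.model.samples_per_pop)]

    def full_alignment(self) -> np.ndarray:
        """(n_haplotypes, window_length) nucleotide-code matrix."""
        n = self.matrix.shape[0]
        L = self.model.window_length
        rng = np.random.default_rng(self.seed)
        background = rng.choice(4, size=L, p=self.model.base_frequencies).astype(np.int8)
        aln = np.tile(background, (n, 1))
        aln[:, self.positions] = self.matrix
        return aln

    def to_fasta(self, path) -> None:
        aln = self.full_alignment()
        with open(path, "w") as fh:
            for name, row in zip(self.haplotype_names, aln):
                fh.write(f">{name}\n{''.join(_NUC[row])}\n")


_ASCII_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ASCII_CODE[ord(_c)] = _i


def _nucleotide_matrix(ts: tskit.TreeSequence) -> tuple[np.ndarray, np.ndarray]:
    """Decode a mutated tree sequence into (haplotype x site) nucleotide codes.

    The allele list of each site is its ancestral state followed by the
    distinct derived states in order of appearance -- the ordering used
    by ``genotype_matrix``.  Sites with a single mutation (the vast
    majority) are decoded vectorized; multi-mutation sites fall back to
    a per-site reconstruction.
    """
    n_sites = ts.num_sites
    G = ts.genotype_matrix()  # (sites, samples), allele indices per site
    tables = ts.tables
    positions = tables.sites.position.astype(np.int64)
    anc_raw = tables.sites.ancestral_state
    der_raw = tables.mutations.derived_state
    if len(anc_raw) != n_sites or len(der_raw) != ts.num_mutations:
        raise ValueError("expected single-character allele states (nucleotide model)")
    anc_codes = _ASCII_CODE[anc_raw]
    der_codes = _ASCII_CODE[der_raw]
    mut_site = tables.mutations.site
    code_table = np.zeros((n_sites, 5), dtype=np.int8)
    code_table[:, 0] = anc_codes
    muts_per_site = np.bincount(mut_site, minlength=n_sites)
    single = np.nonzero(muts_per_site == 1)[0]
    code_table[single, 1] = der_codes[np.searchsorted(mut_site, single)]
    for s in np.nonzero(muts_per_site > 1)[0]:
        lo, hi = np.searchsorted(mut_site, [s, s + 1])
        alleles = [int(anc_codes[s])]
        for d in der_codes[lo:hi]:
            if d not in alleles:
                alleles.append(int(d))
        code_table[s, : len(alleles)] = alleles
    matrix = code_table[np.arange(n_sites)[:, None], G].T  # (samples, sites)
    return np.ascontiguousarray(matrix), positions


def _split_seed(seed: int | None, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n, dtype=np.uint64) % (2**31 - 2) + 1


def _mutate(ts: tskit.TreeSequence, model: DemographicModel, seed: int) -> tskit.TreeSequence:
    return msprime.sim_mutations(
        ts,
        rate=model.mutation_scale,
        model=msprime.HKY(
            kappa=model.kappa, equilibrium_frequencies=list(model.base_frequencies)
        ),
        random_seed=int(seed),
    )


def simulate_window(
    model: DemographicModel, seed: int | None = None, label: str = "Background"
) -> SimulatedWindow:
    """Simulate a single window; deterministic given ``seed``."""
    anc_seed, mut_seed = _split_seed(seed, 2)
    ts = msprime.sim_ancestry(
        samples={g: model.samples_per_pop for g in core.GROUP_NAMES},
        ploidy=1,
        demography=model.to_demography(),
        sequence_length=model.window_length,
        recombination_rate=model.rho,
        random_seed=int(anc_seed),
    )
    mts = _mutate(ts, model, mut_seed)
    matrix, positions = _nucleotide_matrix(mts)
    return SimulatedWindow(
        matrix=matrix, positions=positions, model=model, label=label, seed=int(mut_seed)
    )


def simulate_windows(
    model: DemographicModel,
    n: int,
    seed: int | None = None,
    label: str = "Background",
) -> Iterator[SimulatedWindow]:
    """Simulate ``n`` windows of one model as a reproducible batch.

    Genealogies are drawn as msprime replicates of a single seeded run;
    each window receives its own mutation seed, which also seeds its
    invariant-site fill in :meth:`SimulatedWindow.full_alignment`.
    """
    if n < 1:
        return
    seeds = _split_seed(seed, n + 1)
    replicates = msprime.sim_ancestry(
        samples={g: model.samples_per_pop for g in core.GROUP_NAMES},
        ploidy=1,
        demography=model.to_demography(),
        sequence_length=model.window_length,
        recombination_rate=model.rho,
        random_seed=int(seeds[0]),
        num_replicates=n,
    )
    for ts, mut_seed in zip(replicates, seeds[1:]):
        mts = _mutate(ts, model, mut_seed)
        matrix, positions = _nucleotide_matrix(mts)
        yield SimulatedWindow(
            matrix=matrix, positions=positions, model=model, label=label, seed=int(mut_seed)
        )


# -- per-window statistics (shared by the evaluation pipelines) ------------

_STAT_COLUMNS = [
    "label",
    "n_sites",
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


def window_statistics_row(window: SimulatedWindow, *, minimal: bool = False) -> dict:
    """D, f estimators, pi and d_XY of one simulated window.

    ``minimal=True`` computes only the columns the d_XY outlier test
    consumes (pattern statistics plus P2-P3 d_XY), which speeds up
    large model surveys.
    """
    spp = window.model.samples_per_pop
    labels = window.group_labels
    table = core.polarize_sites(window.matrix, labels, positions=window.positions)
    res = core.all_statistics(table)
    n_invariant = window.model.window_length - window.matrix.shape[1]
    rows = {g: slice(k * spp, (k + 1) * spp) for k, g in enumerate(core.GROUP_NAMES)}
    row = {
        "label": window.label,
        "n_sites": window.matrix.shape[1],
        "sitesUsed": res["n_sites"],
        "D": res["D"].value,
        "fG": res["fG"].value if res["fG"] is not None else None,
        "fhom": res["fhom"].value,
        "fd": res["fd"].value,
        "S": res["S"],
    }
    if not minimal:
        for g in ("P1", "P2", "P3"):
            row[f"pi_{g}"] = _windows.nucleotide_diversity(
                window.matrix[rows[g]], n_invariant=n_invariant
            )
        for a, b in (("P1", "P2"), ("P1", "P3")):
            row[f"dxy_{a}{b}"] = _windows.dxy(
                window.matrix[rows[a]], window.matrix[rows[b]], n_invariant=n_invariant
            )
    row["dxy_P2P3"] = _windows.dxy(
        window.matrix[rows["P2"]], window.matrix[rows["P3"]], n_invariant=n_invariant
    )
    return row


# -- combined Background/Alternate datasets --------------------------------


@dataclass
class CombinedModelSpec:
    """A Background model optionally mixed with complete-sharing windows."""

    background: DemographicModel
    alternate: DemographicModel | None = None
    n_background: int = 9000
    n_alternate: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.alternate is None and self.n_alternate:
            raise ValueError("null models have no Alternate windows; set n_alternate=0")
        if self.alternate is not None:
            if self.n_alternate < 1:
                raise ValueError("combined models require n_alternate >= 1")
            if self.alternate.topology != "alternate":
                raise ValueError("the alternate model must have the alternate topology")
        if self.n_background < 1:
            raise ValueError("n_background must be >= 1")

    @property
    def n_windows(self) -> int:
        return self.n_background + self.n_alternate


@dataclass
class CombinedDataset:
    """Labeled per-window statistics of a combined simulation."""

    table: pd.DataFrame
    spec: CombinedModelSpec

    @property
    def n_windows(self) -> int:
        return len(self.table)


def simulate_combined(spec: CombinedModelSpec, *, minimal: bool = False) -> CombinedDataset:
    """Simulate a labeled Background/Alternate dataset and its statistics.

    Windows are simulated in two seeded batches (Background first) and
    statistics are computed per window; the row order interleaves
    nothing, so window ids 0..n_background-1 are Background.
    """
    bg_seed, alt_seed = _split_seed(spec.seed, 2)
    rows = [
        window_statistics_row(w, minimal=minimal)
        for w in simulate_windows(
            spec.background, spec.n_background, int(bg_seed), label="Background"
        )
    ]
    if spec.alternate is not None:
        rows.extend(
            window_statistics_row(w, minimal=minimal)
            for w in simulate_windows(
                spec.alternate, spec.n_alternate, int(alt_seed), label="Alternate"
            )
        )
    columns = [c for c in _STAT_COLUMNS if not minimal or not c.startswith(("pi_", "dxy_P1"))]
    table = pd.DataFrame(rows, columns=columns)
    table.insert(0, "window", np.arange(len(table)))
    return CombinedDataset(table=table, spec=spec)


# -- the estimator grid ----------------------------------------------------

DEFAULT_F_VALUES = tuple(np.round(np.linspace(0.0, 1.0, 11), 10))


def build_estimator_grid(
    directions: Sequence[str] = DIRECTIONS,
    f_values: Sequence[float] = DEFAULT_F_VALUES,
    t_gf_values: Sequence[float] = (0.1, 0.5),
    window_lengths: Sequence[int] = (1000, 5000, 10000),
    rhos: Sequence[float] = (0.001, 0.01, 0.1),
    windows_per_setting: int = 100,
    seed: int | None = None,
) -> Iterator[SimulatedWindow]:
    """Yield windows over the estimator-accuracy grid.

    The full design crosses two gene-flow directions, 11 admixture
    proportions f in 0..1, two admixture times (0.1 and 0.5), three
    window sizes and three per-bp recombination rates, with split times
    fixed at t12 = 1, t23 = 2 and root 3 (all in 4N units) and 100
    windows per setting.  Any subset of the axes may be passed for
    desk-scale runs; an empty selection is an error.  Each window's
    model records the true f and direction.
    """
    settings = list(itertools.product(directions, t_gf_values, window_lengths, rhos, f_values))
    if not settings or windows_per_setting < 1:
        raise ValueError("empty estimator-grid selection")
    seeds = _split_seed(seed, len(settings))
    for (direction, t_gf, length, rho, f), s in zip(settings, seeds):
        model = DemographicModel.background(
            t12=1.0,
            t23=2.0,
            admixture=AdmixtureEvent(direction=direction, time=t_gf, proportion=f),
            window_length=int(length),
            rho=float(rho),
        )
        yield from simulate_windows(model, windows_per_setting, int(s))


def estimator_grid_statistics(**grid_kwargs) -> pd.DataFrame:
    """Per-window statistics over an estimator grid (tidy table).

    Columns: direction, t_gf, window_length, rho, f, window, then the
    statistics of :func:`window_statistics_row`.
    """
    rows = []
    counter = itertools.count()
    for w in build_estimator_grid(**grid_kwargs):
        adm = w.model.admixture
        row = {
            "direction": adm.direction,
            "t_gf": adm.time,
            "window_length": w.model.window_length,
            "rho": w.model.rho,
            "f": adm.proportion,
            "window": next(counter),
        }
        row.update(window_statistics_row(w))
        rows.append(row)
    return pd.DataFrame(rows)


# -- the model survey grid -------------------------------------------------

SCENARIOS = ("null", "geneflow_p3_to_p2", "geneflow_p2_to_p3", "structure")


@dataclass(frozen=True)
class ModelPair:
    """One parameterization of the model survey."""

    scenario: str
    model_id: str
    params: dict
    background: DemographicModel
    alternate: DemographicModel | None

    def to_spec(
        self, n_background: int = 9000, n_alternate: int = 1000, seed: int | None = None
    ) -> CombinedModelSpec:
        if self.alternate is None:
            n_background, n_alternate = n_background + n_alternate, 0
        return CombinedModelSpec(
            background=self.background,
            alternate=self.alternate,
            n_background=n_background,
            n_alternate=n_alternate,
            seed=seed,
        )


def model_grid_tables(
    scenario: str,
    *,
    rho: float = 0.01,
    window_length: int = 5000,
    samples_per_pop: int = 8,
) -> list[ModelPair]:
    """Enumerate the split-time grid of one scenario.

    Times run over 0.2, 0.4, ..., 2.0 (4N units) with the root fixed at
    3.0.  Null models are the 45 ordered pairs t12 < t23; each non-null
    scenario adds a third time (t_GF below t12 for gene flow, t_STR
    above t23 for structure), giving the 120 ordered triples.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    kw = dict(rho=rho, window_length=window_length, samples_per_pop=samples_per_pop)
    pairs: list[ModelPair] = []
    if scenario == "null":
        for i, (t12, t23) in enumerate(itertools.combinations(GRID_TIMES, 2)):
            pairs.append(
                ModelPair(
                    scenario=scenario,
                    model_id=f"null-{i:03d}",
                    params={"t12": t12, "t23": t23},
                    background=DemographicModel.background(t12, t23, **kw),
                    alternate=None,
                )
            )
        return pairs
    for i, (ta, tb, tc) in enumerate(itertools.combinations(GRID_TIMES, 3)):
        if scenario == "geneflow_p3_to_p2":
            t_gf, t12, t23 = ta, tb, tc
            params = {"t12": t12, "t23": t23, "t_gf": t_gf}
            alternate = DemographicModel.alternate(t_gf, t23, **kw)
        elif scenario == "geneflow_p2_to_p3":
            t_gf, t12, t23 = ta, tb, tc
            params = {"t12": t12, "t23": t23, "t_gf": t_gf}
            alternate = DemographicModel.alternate(t_gf, t12, **kw)
        else:  # structure
            t12, t23, t_str = ta, tb, tc
            params = {"t12": t12, "t23": t23, "t_str": t_str}
            alternate = DemographicModel.alternate(t23, t_str, t_structure=t_str, **kw)
        pairs.append(
            ModelPair(
                scenario=scenario,
                model_id=f"{scenario}-{i:03d}",
                params=params,
                background=DemographicModel.background(params["t12"], params["t23"], **kw),
                alternate=alternate,
            )
        )
    return pairs


def subsample_models(pairs: Sequence[ModelPair], k: int) -> list[ModelPair]:
    """Deterministic evenly spaced subsample of a model grid."""
    if k >= len(pairs):
        return list(pairs)
    if k < 1:
        raise ValueError("k must be >= 1")
    idx = np.unique(np.round(np.linspace(0, len(pairs) - 1, k)).astype(int))
    return [pairs[i] for i in idx]


def write_dataset(windows: Iterable[SimulatedWindow], outdir, *, fasta: bool = True) -> Path:
    """Write per-window FASTA alignments and a tab-separated manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, w in enumerate(windows):
        name = f"window_{i:05d}"
        if fasta:
            w.to_fasta(outdir / f"{name}.fa")
        m = w.model
        adm = m.admixture
        records.append(
            {
                "window": name,
                "label": w.label,
                "topology": m.topology,
                "t12": m.t12,
                "t23": m.t23,
                "t_root": m.t_root,
                "direction": adm.direction if adm else "NA",
                "t_gf": adm.time if adm else "NA",
                "f": adm.proportion if adm else "NA",
                "t_structure": m.t_structure if m.t_structure is not None else "NA",
                "window_length": m.window_length,
                "rho": m.rho,
                "mutation_scale": m.mutation_scale,
                "seed": w.seed,
            }
        )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(records).to_csv(manifest, sep="\t", index=False)
    return manifest
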