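"""Forward Wright-Fisher simulation of a population split.

The demographic scenario is fixed in structure and parameterised by the base
population size ``N`` (diploid individuals):

1. *burn-in* — a single randomly mating population of ``N`` individuals,
   started monomorphic, evolves for ``8N`` generations so the split happens
   at mutation-drift equilibrium;
2. *split* — the individuals are randomly partitioned into two demes of
   ``N/2`` each;
3. *growth* — with no migration, each deme grows by one individual per
   generation for ``N/2`` generations (deme size at ``t`` generations
   post-split is ``N/2 + t``);
4. *stationary* — each deme mates randomly at constant size ``N`` for a
   further ``4N`` generations.

Reproduction is neutral Wright-Fisher: every offspring draws two parents
uniformly at random with replacement (selfing allowed) and receives one
recombinant gamete from each.  Per gamete the number of crossovers is
Poisson(L*rho) with breakpoints uniform on (0, L), and the number of new
mutations is Poisson(L*mu) at uniform continuous positions; a position that
collides with an existing segregating site is redrawn, so the model is
effectively infinite-sites.

The population state is a dense boolean matrix (haplotypes x segregating
sites) plus a parallel array of site positions.  Sites fixed or lost in the
whole (meta)population are pruned every generation; after the split a site
fixed in one deme and lost in the other is remembered as a fixed difference
and re-materialised in the output with census frequencies 1 and 0.

Output is the *census* derived-allele frequency of every site in each deme
at the final generation — no sampling step — from which windowed
uncorrected Hudson F_ST distributions are summarised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fst import hudson_components_arrays, window_fst_from_components

__all__ = [
    "SimConfig",
    "ReplicateResult",
    "SimResult",
    "simulate",
    "simulate_replicate",
    "summarize_windows",
    "replicate_to_matrix",
    "window_fst_census",
    "PRESET_N200",
    "PRESET_N400",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulation run.

    N is the base diploid population size (the split demes start at N/2 and
    end at N each); L the sequence length in bp; mu and rho the per-bp
    per-generation mutation and recombination rates.
    """

    N: int = 200
    L: int = 2_000_000
    mu: float = 1e-7
    rho: float = 1e-7
    replicates: int = 10
    seed: int = 0
    window_sizes: tuple[int, ...] = (1_000, 10_000)
    haploid: bool = False
    keep_haplotypes: bool = False  # retain final-generation haplotypes (VCF export)
    # schedule overrides, mainly for diagnostics (None = the standard
    # schedule: 8N burn-in, N/2 growth, 4N stationary generations)
    burn_generations: int | None = None
    growth_generations: int | None = None
    stationary_generations: int | None = None

    def __post_init__(self) -> None:
        if self.N < 2 or self.N % 2:
            raise ValueError(f"N must be an even integer >= 2, got {self.N}")
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.mu < 0 or self.rho < 0:
            raise ValueError("mu and rho must be non-negative")
        g = self.generations[1]
        if g > self.N // 2:
            raise ValueError("growth phase cannot exceed N/2 generations (deme size caps at N)")

    @property
    def generations(self) -> tuple[int, int, int]:
        """(burn-in, growth, stationary) generation counts; defaults 8N, N/2, 4N."""
        burn = 8 * self.N if self.burn_generations is None else self.burn_generations
        growth = self.N // 2 if self.growth_generations is None else self.growth_generations
        stat = 4 * self.N if self.stationary_generations is None else self.stationary_generations
        return burn, growth, stat


# The two presets used throughout: N=200 runs 2 Mb sequences, N=400 halves
# the sequence length (and doubles the replicate count in the full design).
PRESET_N200 = SimConfig(N=200, L=2_000_000, replicates=10)
PRESET_N400 = SimConfig(N=400, L=1_000_000, replicates=20)


@dataclass
class ReplicateResult:
    """Final-generation census state of one replicate.

    positions are sorted bp coordinates in [0, L); freq1/freq2 the census
    derived-allele frequencies of the two demes at those positions (fixed
    differences appear as 1 vs 0).
    """

    positions: np.ndarray
    freq1: np.ndarray
    freq2: np.ndarray
    n_haplotypes: tuple[int, int]
    # final-generation haplotype matrices (haplotypes x sites, aligned to
    # positions, fixed differences materialized); None unless requested
    haplotypes: tuple[np.ndarray, np.ndarray] | None = None


@dataclass
class SimResult:
    config: SimConfig
    replicates: list[ReplicateResult] = field(default_factory=list)

    def window_fst(self, window: int) -> np.ndarray:
        """Pooled defined window F_ST values (uncorrected) over replicates."""
        vals = [
            window_fst_census(rep.positions, rep.freq1, rep.freq2, window, self.config.L)
            for rep in self.replicates
        ]
        return np.concatenate(vals) if vals else np.empty(0)


class _Population:
    """Dense-matrix haplotype store for one or two demes.

    haps[d] is a (2 * size_d, S) boolean matrix over the S currently tracked
    segregating sites; positions is the shared length-S coordinate array
    (unsorted; sorted only at output time).  fixed_diff collects positions
    of sites fixed in deme 0 and lost in deme 1 (or vice versa) after the
    split, which no longer need per-haplotype storage.
    """

    def __init__(self, rng: np.random.Generator, L: float, ploidy: int = 2) -> None:
        self.rng = rng
        self.L = float(L)
        self.ploidy = ploidy
        self.positions = np.empty(0)
        self.haps: list[np.ndarray] = []
        self.fixed_diff: list[tuple[float, int]] = []  # (position, deme fixed in)
        self.fixed_count = 0  # sites pruned as fixed population-wide (diagnostics)

    # -- reproduction -------------------------------------------------

    def _gametes(
        self, parent_haps: np.ndarray, hap_a: np.ndarray, hap_b: np.ndarray, rho: float
    ) -> np.ndarray:
        """One recombinant gamete per (hap_a[i], hap_b[i]) parental pair.

        hap_a/hap_b index rows of parent_haps; for a diploid parent they are
        its two haplotypes, for a haploid cross they are two distinct
        parents' genomes.
        """
        n_offspring = hap_a.size
        phase = self.rng.integers(2, size=n_offspring)
        n_cross = self.rng.poisson(self.L * rho, size=n_offspring)
        out = parent_haps[np.where(phase == 0, hap_a, hap_b)]  # zero-crossover fast path
        for i in np.nonzero(n_cross)[0]:
            cuts = self.rng.uniform(0.0, self.L, size=n_cross[i])
            cuts.sort()
            # segment parity decides which parental haplotype donates a site
            donor = (np.searchsorted(cuts, self.positions) + phase[i]) % 2
            out[i] = np.where(donor == 0, parent_haps[hap_a[i]], parent_haps[hap_b[i]])
        return out

    def _mutate(self, new_haps: list[np.ndarray], mu: float) -> None:
        """Add Poisson(total gametes * L * mu) new singleton columns."""
        total_gametes = sum(h.shape[0] for h in new_haps)
        n_new = self.rng.poisson(total_gametes * self.L * mu)
        if n_new == 0:
            return
        pos = self.rng.uniform(0.0, self.L, size=n_new)
        while np.isin(pos, self.positions).any():  # infinite-sites redraw
            clash = np.isin(pos, self.positions)
            pos[clash] = self.rng.uniform(0.0, self.L, size=clash.sum())
        carrier = self.rng.integers(total_gametes, size=n_new)
        cols = []
        offset = 0
        for h in new_haps:
            block = np.zeros((h.shape[0], n_new), dtype=bool)
            local = (carrier >= offset) & (carrier < offset + h.shape[0])
            block[carrier[local] - offset, np.nonzero(local)[0]] = True
            cols.append(block)
            offset += h.shape[0]
        self.positions = np.concatenate([self.positions, pos])
        for d in range(len(new_haps)):
            new_haps[d] = np.hstack([new_haps[d], cols[d]])

    def step(self, sizes: list[int], mu: float, rho: float, haploid: bool = False) -> None:
        """Advance one generation; sizes are next-generation deme sizes.

        Diploid: each offspring draws two parents uniformly with replacement
        and receives one recombinant gamete from each.  Haploid: each
        offspring genome is one recombinant gamete of two uniformly drawn
        parental genomes.
        """
        new_haps = []
        for d, size in enumerate(sizes):
            parent_haps = self.haps[d]
            if haploid:
                n_parents = parent_haps.shape[0]
                pa = self.rng.integers(n_parents, size=size)
                pb = self.rng.integers(n_parents, size=size)
                new_haps.append(self._gametes(parent_haps, pa, pb, rho))
            else:
                n_parents = parent_haps.shape[0] // 2
                mothers = self.rng.integers(n_parents, size=size)
                fathers = self.rng.integers(n_parents, size=size)
                g_mat = self._gametes(parent_haps, 2 * mothers, 2 * mothers + 1, rho)
                g_pat = self._gametes(parent_haps, 2 * fathers, 2 * fathers + 1, rho)
                nh = np.empty((2 * size, g_mat.shape[1]), dtype=bool)
                nh[0::2] = g_mat
                nh[1::2] = g_pat
                new_haps.append(nh)
        self._mutate(new_haps, mu)
        self.haps = new_haps
        self._prune()

    # -- pruning -------------------------------------------------------

    def _prune(self) -> None:
        if self.positions.size == 0:
            return
        counts = [h.sum(axis=0) for h in self.haps]
        totals = [h.shape[0] for h in self.haps]
        lost = np.all([c == 0 for c in counts], axis=0)
        fixed = np.all([c == t for c, t in zip(counts, totals)], axis=0)
        self.fixed_count += int(fixed.sum())
        if len(self.haps) == 2:
            fd01 = (counts[0] == totals[0]) & (counts[1] == 0)
            fd10 = (counts[0] == 0) & (counts[1] == totals[1])
            for p in self.positions[fd01]:
                self.fixed_diff.append((float(p), 0))
            for p in self.positions[fd10]:
                self.fixed_diff.append((float(p), 1))
            drop = lost | fixed | fd01 | fd10
        else:
            drop = lost | fixed
        if drop.any():
            keep = ~drop
            self.positions = self.positions[keep]
            self.haps = [h[:, keep] for h in self.haps]

    # -- demography ----------------------------------------------------

    def split(self) -> None:
        """Randomly partition the single deme's individuals into two halves."""
        (h,) = self.haps
        k = self.ploidy
        n = h.shape[0] // k
        perm = self.rng.permutation(n)
        idx = (perm[:, None] * k + np.arange(k)).ravel()
        shuffled = h[idx]
        cut = (n // 2) * k
        self.haps = [shuffled[:cut], shuffled[cut:]]

    def census(self, with_haplotypes: bool = False):
        """Sorted positions with per-deme census frequencies (incl. fixed diffs)."""
        counts = [h.sum(axis=0) for h in self.haps]
        totals = [h.shape[0] for h in self.haps]
        pos = list(self.positions)
        f1 = list(counts[0] / totals[0])
        f2 = list(counts[1] / totals[1])
        for p, deme in self.fixed_diff:
            pos.append(p)
            f1.append(1.0 if deme == 0 else 0.0)
            f2.append(0.0 if deme == 0 else 1.0)
        pos_a = np.asarray(pos)
        order = np.argsort(pos_a)
        out = (pos_a[order], np.asarray(f1)[order], np.asarray(f2)[order])
        if not with_haplotypes:
            return out
        mats = []
        n_fd = len(self.fixed_diff)
        for d, h in enumerate(self.haps):
            fd_cols = np.zeros((h.shape[0], n_fd), dtype=bool)
            for j, (_, deme) in enumerate(self.fixed_diff):
                fd_cols[:, j] = deme == d
            full = np.hstack([h, fd_cols])
            mats.append(full[:, order])
        return out + (tuple(mats),)


def simulate_replicate(
    config: SimConfig,
    rng: np.random.Generator,
    checkpoints: list[int] | None = None,
    checkpoint_sink: list[ReplicateResult] | None = None,
) -> ReplicateResult:
    """Run one replicate of the split demography to its final generation.

    ``checkpoints`` (generations after the end of the growth phase) may be
    given to record intermediate census states into ``checkpoint_sink``,
    used by divergence-over-time diagnostics.
    """
    ploidy = 1 if config.haploid else 2
    pop = _Population(rng, config.L, ploidy=ploidy)
    pop.haps = [np.zeros((config.N * ploidy, 0), dtype=bool)]

    burn, growth, stationary = config.generations
    hap = config.haploid
    for _ in range(burn):
        pop.step([config.N], config.mu, config.rho, haploid=hap)
        assert pop.haps[0].shape[0] == config.N * ploidy
    pop.split()
    half = config.N // 2
    for t in range(1, growth + 1):
        pop.step([half + t, half + t], config.mu, config.rho, haploid=hap)
        # deme-size schedule: N/2 + t individuals per deme, exactly
        assert all(h.shape[0] == (half + t) * ploidy for h in pop.haps)
    checkpoints = checkpoints or []
    sink = checkpoint_sink if checkpoint_sink is not None else []
    if 0 in checkpoints:
        sink.append(_snapshot(pop))
    final_size = half + growth  # == N under the standard schedule
    for t in range(1, stationary + 1):
        pop.step([final_size, final_size], config.mu, config.rho, haploid=hap)
        assert all(h.shape[0] == final_size * ploidy for h in pop.haps)
        if t in checkpoints:
            sink.append(_snapshot(pop))
    return _snapshot(pop, with_haplotypes=config.keep_haplotypes)


def _snapshot(pop: _Population, with_haplotypes: bool = False) -> ReplicateResult:
    if with_haplotypes:
        pos, f1, f2, mats = pop.census(with_haplotypes=True)
    else:
        pos, f1, f2 = pop.census()
        mats = None
    return ReplicateResult(
        positions=pos,
        freq1=f1,
        freq2=f2,
        n_haplotypes=(pop.haps[0].shape[0], pop.haps[1].shape[0]),
        haplotypes=mats,
    )


def simulate(config: SimConfig) -> SimResult:
    """Run all replicates of ``config`` with independent seeded streams."""
    ss = np.random.SeedSequence(config.seed)
    result = SimResult(config=config)
    for child in ss.spawn(config.replicates):
        rng = np.random.default_rng(child)
        result.replicates.append(simulate_replicate(config, rng))
    return result


def replicate_to_matrix(rep: ReplicateResult, chrom: str = "sim1"):
    """Convert a haplotype-keeping replicate to a GenotypeMatrix + panel.

    Continuous site positions are floored to 1-based integer coordinates
    for VCF; the rare site whose floored position collides with an earlier
    one is dropped (a few per Mb at most).  Demes become populations
    ``deme1``/``deme2`` with two haplotypes per synthetic diploid sample.
    """
    from .data_model import GenotypeMatrix, PopulationPanel, Variant

    if rep.haplotypes is None:
        raise ValueError("replicate was run without keep_haplotypes")
    h1, h2 = rep.haplotypes
    pos_int = np.floor(rep.positions).astype(int) + 1
    keep = np.concatenate([[True], np.diff(pos_int) > 0]) if pos_int.size else np.zeros(0, bool)
    pos_int = pos_int[keep]
    hap = np.hstack([h1[:, keep].T.astype(np.int8), h2[:, keep].T.astype(np.int8)])
    variants = [
        Variant(chrom=chrom, pos=int(p), ref="A", alt="T", ancestral="A")
        for p in pos_int
    ]
    n1 = h1.shape[0] // 2
    n2 = h2.shape[0] // 2
    sample_ids = [f"deme1_{i:04d}" for i in range(n1)] + [f"deme2_{i:04d}" for i in range(n2)]
    panel = PopulationPanel(
        assignment={s: ("deme1" if s.startswith("deme1") else "deme2") for s in sample_ids}
    )
    matrix = GenotypeMatrix(variants=variants, haplotypes=hap, sample_ids=sample_ids)
    return matrix, panel


def window_fst_census(
    positions: np.ndarray,
    freq1: np.ndarray,
    freq2: np.ndarray,
    window: int,
    L: int,
) -> np.ndarray:
    """Defined uncorrected window F_ST values from census frequencies.

    Windows are [k*w, (k+1)*w) for k = 0 .. floor(L/w)-1; a trailing remnant
    shorter than w is excluded.  Windows whose summed denominator is zero
    (no variant, or all monomorphic-in-both) are dropped from the returned
    array — they are undefined, not zero.
    """
    num, den = hudson_components_arrays(freq1, None, freq2, None, corrected=False)
    fst, _ = window_fst_from_components(positions, num, den, window, L)
    return fst[~np.isnan(fst)]


def summarize_windows(result: SimResult, window: int) -> dict:
    """Mean and histogram (bin width 0.01) of pooled window F_ST values."""
    vals = result.window_fst(window)
    edges = np.arange(0.0, 1.01 + 1e-9, 0.01)
    hist, _ = np.histogram(np.clip(vals, 0, 1.01 - 1e-12), bins=edges)
    per_rep_means = [
        float(np.mean(window_fst_census(r.positions, r.freq1, r.freq2, window, result.config.L)))
        for r in result.replicates
    ]
    return {
        "window": window,
        "n_windows": int(vals.size),
        "mean": float(vals.mean()) if vals.size else float("nan"),
        "variance": float(vals.var(ddof=1)) if vals.size > 1 else float("nan"),
        "replicate_means": per_rep_means,
        "bin_edges": edges.tolist(),
        "counts": hist.tolist(),
    }
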