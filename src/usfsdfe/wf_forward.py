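"""Forward Wright-Fisher simulation of coding sequence under a full DFE.

The simulated chromosome mirrors a compact "gene model" layout: seven genes
of five 300-bp exons separated by 100-bp neutral introns, each gene followed
by 8,100 bp of neutral spacer.  Exonic mutations are selected
(nonsynonymous) with probability 2/3 — drawing a scaled effect from the DFE
— and neutral (synonymous) otherwise; intron and spacer mutations are always
neutral but are simulated because they mediate linked selection.

Reproduction is standard Wright-Fisher: offspring gametes choose parents
multinomially in proportion to multiplicative diploid fitness
(1, 1 + h*s, 1 + s per site, ``h = 1/2`` by default, fitness floored at 0),
with Poisson crossovers per meiosis and Poisson mutation over sites.
Mutation follows the infinite-sites idealisation within finite coordinates:
a mutation landing on an occupied position redraws a free position of the
same site class, so derived-allele polarization is exact.

Population-size rescaling by ``Q`` (simulate ``N/Q`` diploids with ``mu``,
``r`` and ``s`` multiplied by ``Q`` and time divided by ``Q``) preserves all
scaled compound parameters (theta, rho, gamma, T/N) and makes desk-scale
runs of the large-``N_e`` design feasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from .dfe_model import DFEParams, make_dfe, sample_gamma
from .usfs_summaries import USFSDataset

__all__ = [
    "ChromosomeGeometry",
    "SimulationConfig",
    "Variant",
    "Substitution",
    "ReplicateResult",
    "full_scale_config",
    "desk_scale_config",
    "build_chromosome",
    "rescale_config",
    "WrightFisherSimulation",
    "run_replicate",
    "sample_usfs_from_replicates",
    "write_replicate_tables",
    "read_simulation_config",
]

# site-class codes in the chromosome map
SPACER, INTRON, EXON = 0, 1, 2
CLASS_NAMES = {0: "spacer", 1: "intron", 2: "syn", 3: "nonsyn"}
CLASS_CODES = {v: k for k, v in CLASS_NAMES.items()}


@dataclass(frozen=True)
class ChromosomeGeometry:
    """Layout of the simulated chromosome."""

    n_genes: int = 7
    exons_per_gene: int = 5
    exon_bp: int = 300
    intron_bp: int = 100
    spacer_bp: int = 8100
    fraction_selected_in_exons: float = 2.0 / 3.0

    @property
    def gene_bp(self) -> int:
        return (self.exons_per_gene * self.exon_bp
                + (self.exons_per_gene - 1) * self.intron_bp)

    @property
    def exonic_bp(self) -> int:
        return self.n_genes * self.exons_per_gene * self.exon_bp

    @property
    def total_bp(self) -> int:
        return self.n_genes * (self.gene_bp + self.spacer_bp)

    @property
    def L_sel(self) -> float:
        """Effective nonsynonymous site count."""
        return self.exonic_bp * self.fraction_selected_in_exons

    @property
    def L_neut(self) -> float:
        """Effective (exonic) synonymous site count."""
        return self.exonic_bp * (1.0 - self.fraction_selected_in_exons)


@dataclass(frozen=True)
class SimulationConfig:
    N: int = 10_000
    mu: float = 2.5e-7
    rec: float = 2.5e-7
    geometry: ChromosomeGeometry = field(default_factory=ChromosomeGeometry)
    dfe: DFEParams = field(default_factory=lambda: make_dfe(0.3, -2000.0, 0.0, 0.0))
    burnin_gens: int = 85_000
    divergence_gens: int = 200_000
    sample_n: int = 20
    dominance: float = 0.5
    rescale_Q: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.N < 50:
            raise ValueError("population size N must be >= 50 (after any rescaling)")
        if self.burnin_gens < 0 or self.divergence_gens < 0:
            raise ValueError("phase lengths must be non-negative")

    @property
    def theta_site(self) -> float:
        return 4.0 * self.N * self.mu

    @property
    def rho_site(self) -> float:
        return 4.0 * self.N * self.rec


def full_scale_config(dfe: DFEParams, seed: Optional[int] = None) -> SimulationConfig:
    """The full-scale study design: N_e = 10,000, mu = r = 2.5e-7,
    85,000 generations of burn-in and a 200,000-generation divergence phase.
    Cluster-scale as given; rescale with :func:`rescale_config` for desk use.
    """
    return SimulationConfig(dfe=dfe, seed=seed)


def desk_scale_config(dfe: DFEParams, Q: float = 10.0,
                      burnin_gens: Optional[int] = None,
                      divergence_gens: Optional[int] = None,
                      seed: Optional[int] = None) -> SimulationConfig:
    """Rescaled profile of the full design (default Q = 10, burn-in 10N')."""
    cfg = rescale_config(full_scale_config(dfe, seed=seed), Q)
    if burnin_gens is None:
        burnin_gens = 10 * cfg.N
    if divergence_gens is None:
        divergence_gens = cfg.divergence_gens
    return replace(cfg, burnin_gens=burnin_gens, divergence_gens=divergence_gens)


def build_chromosome(geometry: ChromosomeGeometry) -> np.ndarray:
    """Per-position site-class codes (spacer / intron / exon)."""
    gene = np.empty(geometry.gene_bp, dtype=np.uint8)
    off = 0
    for e in range(geometry.exons_per_gene):
        gene[off:off + geometry.exon_bp] = EXON
        off += geometry.exon_bp
        if e < geometry.exons_per_gene - 1:
            gene[off:off + geometry.intron_bp] = INTRON
            off += geometry.intron_bp
    unit = np.concatenate([gene, np.full(geometry.spacer_bp, SPACER, dtype=np.uint8)])
    return np.tile(unit, geometry.n_genes)


def rescale_config(config: SimulationConfig, Q: float) -> SimulationConfig:
    """Rescale the design by ``Q``: fewer individuals, faster clocks.

    ``N -> N/Q``, ``mu, rec -> Q*mu, Q*rec``, phase lengths ``-> /Q``.
    Scaled effects ``gamma = 2*N*s`` are stored directly in the DFE, so all
    compound parameters (theta, rho, gamma, T/N) are invariant.
    """
    if Q <= 0:
        raise ValueError("rescaling factor Q must be positive")
    N_new = int(round(config.N / Q))
    if N_new < 50:
        raise ValueError(f"Q = {Q} would leave N = {N_new} < 50 diploids")
    return replace(
        config,
        N=N_new,
        mu=config.mu * Q,
        rec=config.rec * Q,
        burnin_gens=int(round(config.burnin_gens / Q)),
        divergence_gens=int(round(config.divergence_gens / Q)),
        rescale_Q=config.rescale_Q * Q,
    )


@dataclass(frozen=True)
class Variant:
    position: int
    site_class: str          # 'nonsyn' | 'syn' | 'intron' | 'spacer'
    gamma: float
    count: int               # derived copies in the sample of 2*sample_n


@dataclass(frozen=True)
class Substitution:
    site_class: str
    gamma: float
    phase: str               # 'divergence-window' | 'sample-fixed'


@dataclass
class ReplicateResult:
    variants: List[Variant]
    substitutions: List[Substitution]
    L_sel: float
    L_neut: float
    sample_n: int
    seed: Optional[int] = None

    @property
    def n_chrom(self) -> int:
        return 2 * self.sample_n


class WrightFisherSimulation:
    """Mutable forward-simulation state; step one generation at a time.

    Exposes the segregating-variant arrays (``positions``, ``gammas``,
    ``classes``, genotype matrix ``G`` of shape ``(2N, S)``) for inspection,
    which small-population tests use for exact brute-force checks.
    """

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        geom = config.geometry
        self.class_map = build_chromosome(geom)
        self.L = geom.total_bp
        self.n_hap = 2 * config.N
        # per-class position pools for infinite-sites redraws
        self._class_positions = {
            code: np.flatnonzero(self.class_map == code)
            for code in (SPACER, INTRON, EXON)
        }
        self.G = np.zeros((self.n_hap, 0), dtype=bool)
        self.positions = np.empty(0, dtype=np.int64)
        self.gammas = np.empty(0, dtype=float)
        self.classes = np.empty(0, dtype=np.uint8)
        self._occupied = np.zeros(self.L, dtype=bool)
        self.substitutions: List[Substitution] = []
        self.record_substitutions = False
        self._mut_rate = self.n_hap * config.mu * self.L
        self._cross_rate = config.rec * (self.L - 1)
        #: generations between fixation/loss sweeps over the variant columns
        self.purge_interval = 4
        self._gens_since_purge = 0
        self._tail_start = 0

    # -- fitness ----------------------------------------------------------

    #: stand-in for log(0) fitness: a genotype carrying k lethal sites is
    #: penalised k-fold, so the least-loaded genotypes win even when every
    #: individual carries at least one lethal
    _LOG_LETHAL = -1e4

    def _parent_probs(self) -> Optional[np.ndarray]:
        sel = np.flatnonzero(self.gammas != 0.0)
        if sel.size == 0:
            return None
        s = self.gammas[sel] / self.n_hap          # gamma = 2*N*s
        h = self.config.dominance
        w_het = np.maximum(1.0 + h * s, 0.0)
        w_hom = np.maximum(1.0 + s, 0.0)
        log_het = np.where(w_het > 0, np.log(np.where(w_het > 0, w_het, 1.0)),
                           self._LOG_LETHAL)
        log_hom = np.where(w_hom > 0, np.log(np.where(w_hom > 0, w_hom, 1.0)),
                           self._LOG_LETHAL)
        copies = (self.G[0::2][:, sel].astype(np.int8)
                  + self.G[1::2][:, sel].astype(np.int8))
        logw = ((copies == 1) @ log_het) + ((copies == 2) @ log_hom)
        w = np.exp(logw - np.max(logw))
        tot = w.sum()
        if tot <= 0:  # pragma: no cover - cannot happen after the shift
            return None
        return w / tot

    # -- one generation ---------------------------------------------------

    def step(self) -> None:
        rng = self.rng
        N, n_hap = self.config.N, self.n_hap
        probs = self._parent_probs()
        parents = rng.choice(N, size=n_hap, p=probs)
        start = rng.integers(0, 2, size=n_hap)
        child = self.G[2 * parents + start]        # no-crossover inheritance

        # Columns [0, _tail_start) are position-sorted (re-established at
        # each purge), so crossover segments are contiguous slices there; the
        # unsorted tail of recent mutations is handled by a small mask.
        T = self._tail_start
        pos_sorted = self.positions[:T]
        pos_tail = self.positions[T:]
        n_cross = rng.poisson(self._cross_rate, size=n_hap)
        singles = np.flatnonzero(n_cross == 1)     # batched common case
        if singles.size:
            cps = rng.uniform(0.0, self.L, size=singles.size)
            alt_rows = 2 * parents[singles] + 1 - start[singles]
            cuts = np.searchsorted(pos_sorted, cps)
            G = self.G
            for j, row, lo in zip(singles, alt_rows, cuts):
                if lo < T:
                    child[j, lo:T] = G[row, lo:T]
            if pos_tail.size:
                tail_swap = pos_tail[None, :] >= cps[:, None]
                if tail_swap.any():
                    sub = child[singles, T:]
                    np.copyto(sub, G[alt_rows, T:], where=tail_swap)
                    child[singles, T:] = sub
        for j in np.flatnonzero(n_cross >= 2):
            alt = self.G[2 * parents[j] + 1 - start[j]]
            cps = np.sort(rng.uniform(0.0, self.L, size=n_cross[j]))
            bnds = np.concatenate([np.searchsorted(pos_sorted, cps), [T]])
            # odd-numbered segments come from the other parental haplotype
            for seg in range(0, n_cross[j], 2):
                lo, hi = bnds[seg], bnds[seg + 1]
                if lo < hi:
                    child[j, lo:hi] = alt[lo:hi]
            if pos_tail.size:
                parity = np.searchsorted(cps, pos_tail, side="right") % 2
                swap = np.flatnonzero(parity == 1) + T
                if swap.size:
                    child[j, swap] = alt[swap]

        n_new = rng.poisson(self._mut_rate)
        new_pos = self._draw_positions(n_new) if n_new else None
        n_new = 0 if new_pos is None else new_pos.size
        S = child.shape[1]
        G_next = np.empty((n_hap, S + n_new), dtype=bool)
        G_next[:, :S] = child
        pos_next = np.empty(S + n_new, dtype=np.int64)
        gam_next = np.empty(S + n_new, dtype=float)
        cls_next = np.empty(S + n_new, dtype=np.uint8)
        pos_next[:S] = self.positions
        gam_next[:S] = self.gammas
        cls_next[:S] = self.classes

        if n_new:
            pos_next[S:] = new_pos
            G_next[:, S:] = False
            code = self.class_map[pos_next[S:]]
            geom = self.config.geometry
            is_sel = (code == EXON) & (rng.random(n_new)
                                       < geom.fraction_selected_in_exons)
            gam_next[S:] = 0.0
            if is_sel.any():
                gam_next[S:][is_sel] = sample_gamma(self.config.dfe, rng,
                                                    size=int(is_sel.sum()))
            cls_next[S:] = code                    # EXON code doubles as 'syn'
            cls_next[S:][is_sel] = CLASS_CODES["nonsyn"]
            carriers = rng.integers(0, n_hap, size=n_new)
            G_next[carriers, S + np.arange(n_new)] = True

        self.G = G_next
        self.positions = pos_next
        self.gammas = gam_next
        self.classes = cls_next
        self._gens_since_purge += 1
        if self._gens_since_purge >= self.purge_interval:
            self._purge()

    def _purge(self) -> None:
        """Drop lost and fixed variants, record substitutions, re-sort columns.

        Runs every ``purge_interval`` generations: between purges, lost
        columns are all-False and fixed columns all-True, neither of which
        affects relative fitness or inheritance.
        """
        self._gens_since_purge = 0
        counts = np.count_nonzero(self.G, axis=0)
        fixed = counts == self.n_hap
        keep = (counts > 0) & ~fixed
        if fixed.any() and self.record_substitutions:
            for k in np.flatnonzero(fixed):
                self.substitutions.append(Substitution(
                    site_class=CLASS_NAMES[int(self.classes[k])],
                    gamma=float(self.gammas[k]),
                    phase="divergence-window",
                ))
        if not keep.all():
            self._occupied[self.positions[~keep]] = False
        keep_idx = np.flatnonzero(keep)
        order = keep_idx[np.argsort(self.positions[keep_idx], kind="stable")]
        self.G = np.ascontiguousarray(self.G[:, order])
        self.positions = self.positions[order]
        self.gammas = self.gammas[order]
        self.classes = self.classes[order]
        self._tail_start = self.positions.size

    def _draw_positions(self, n_new: int) -> np.ndarray:
        """Uniform positions honouring the infinite-sites redraw rule.

        A mutation landing on an occupied site redraws uniformly among the
        free positions of the same site class; if a class is ever fully
        occupied (only reachable on extremely small, dense test chromosomes)
        the mutation is dropped.
        """
        rng = self.rng
        raw = rng.integers(0, self.L, size=n_new)
        _, first = np.unique(raw, return_index=True)
        dup = np.ones(n_new, dtype=bool)
        dup[first] = False
        bad = dup | self._occupied[raw]
        good = ~bad
        self._occupied[raw[good]] = True
        keep = np.ones(n_new, dtype=bool)
        for k in np.flatnonzero(bad):
            p = int(raw[k])
            pool = self._class_positions[int(self.class_map[p])]
            for _ in range(32):                    # fast path: rejection draws
                if not self._occupied[p]:
                    break
                p = int(pool[rng.integers(0, pool.size)])
            else:
                free = pool[~self._occupied[pool]]
                if free.size == 0:
                    keep[k] = False
                    continue
                p = int(free[rng.integers(0, free.size)])
            raw[k] = p
            self._occupied[p] = True
        return raw[keep] if not keep.all() else raw

    def run(self, generations: int) -> None:
        """Advance ``generations`` steps, ending on a purged, sorted state."""
        for _ in range(generations):
            self.step()
        if self._gens_since_purge:
            self._purge()

    # -- sampling ---------------------------------------------------------

    def sample(self, sample_n: int) -> List[Variant]:
        """Tally derived counts in ``2*sample_n`` genome copies drawn from
        ``sample_n`` distinct diploids (without replacement)."""
        rng = self.rng
        inds = rng.choice(self.config.N, size=sample_n, replace=False)
        rows = np.concatenate([2 * inds, 2 * inds + 1])
        counts = np.count_nonzero(self.G[rows], axis=0)
        out = []
        for k in np.flatnonzero(counts):
            out.append(Variant(
                position=int(self.positions[k]),
                site_class=CLASS_NAMES[int(self.classes[k])],
                gamma=float(self.gammas[k]),
                count=int(counts[k]),
            ))
        return out


def run_replicate(config: SimulationConfig, seed: Optional[int] = None) -> ReplicateResult:
    """Run one forward replicate: burn-in, divergence window, final sample.

    Substitutions are scored only after burn-in; derived alleles fixed in
    the final sample (but still polymorphic in the population) are recorded
    as ``sample-fixed`` substitutions, mirroring the treatment of
    population-frequency-1.0 variants as divergence.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    sim = WrightFisherSimulation(config, rng)
    sim.run(config.burnin_gens)
    sim.record_substitutions = True
    sim.run(config.divergence_gens)

    variants = sim.sample(config.sample_n)
    subs = list(sim.substitutions)
    n_chrom = 2 * config.sample_n
    for v in variants:
        if v.count == n_chrom:
            subs.append(Substitution(site_class=v.site_class, gamma=v.gamma,
                                     phase="sample-fixed"))
    geom = config.geometry
    return ReplicateResult(
        variants=variants,
        substitutions=subs,
        L_sel=geom.L_sel,
        L_neut=geom.L_neut,
        sample_n=config.sample_n,
        seed=seed,
    )


def sample_usfs_from_replicates(replicates: Sequence[ReplicateResult],
                                sample_n: Optional[int] = None,
                                with_divergence: bool = True) -> USFSDataset:
    """Pool replicates into a paired nonsynonymous/synonymous uSFS dataset.

    The neutral class is exonic synonymous sites (introns and spacers are
    simulated for linkage but excluded from the analysis).  Sample-fixed
    variants join the divergence counts; with ``with_divergence=False`` both
    they and the substitution records are dropped.
    """
    if not replicates:
        raise ValueError("no replicates to pool")
    if sample_n is None:
        sample_n = replicates[0].sample_n
    if any(r.sample_n != sample_n for r in replicates):
        raise ValueError("replicates disagree in sample_n")
    n_chrom = 2 * sample_n
    neut = np.zeros(n_chrom - 1, dtype=np.int64)
    sel = np.zeros(n_chrom - 1, dtype=np.int64)
    div_neut = div_sel = 0
    for rep in replicates:
        for v in rep.variants:
            if v.site_class == "syn":
                if v.count < n_chrom:
                    neut[v.count - 1] += 1
                elif with_divergence:
                    div_neut += 1
            elif v.site_class == "nonsyn":
                if v.count < n_chrom:
                    sel[v.count - 1] += 1
                elif with_divergence:
                    div_sel += 1
        if with_divergence:
            for s in rep.substitutions:
                if s.phase != "divergence-window":
                    continue
                if s.site_class == "syn":
                    div_neut += 1
                elif s.site_class == "nonsyn":
                    div_sel += 1
    return USFSDataset(
        neutral_sfs=neut,
        selected_sfs=sel,
        L_neut=sum(r.L_neut for r in replicates),
        L_sel=sum(r.L_sel for r in replicates),
        n_chrom=n_chrom,
        div_neut=div_neut if with_divergence else None,
        div_sel=div_sel if with_divergence else None,
        provenance={"generator": "wf-forward", "n_replicates": len(replicates)},
    )


def write_replicate_tables(rep: ReplicateResult, variants_path,
                           substitutions_path) -> None:
    """Write a replicate as two TSV tables (variants, substitutions)."""
    with open(variants_path, "w") as fh:
        fh.write(f"# sample_n: {rep.sample_n}\n# L_sel: {rep.L_sel}\n"
                 f"# L_neut: {rep.L_neut}\n# seed: {rep.seed}\n")
        fh.write("position\tsite_class\tgamma\tcount\n")
        for v in rep.variants:
            fh.write(f"{v.position}\t{v.site_class}\t{v.gamma!r}\t{v.count}\n")
    with open(substitutions_path, "w") as fh:
        fh.write(f"# seed: {rep.seed}\n")
        fh.write("site_class\tgamma\tphase\n")
        for s in rep.substitutions:
            fh.write(f"{s.site_class}\t{s.gamma!r}\t{s.phase}\n")


_CONFIG_INT_KEYS = {"N", "burnin_gens", "divergence_gens", "sample_n", "seed",
                    "n_genes", "exons_per_gene", "exon_bp", "intron_bp",
                    "spacer_bp"}
_GEOMETRY_KEYS = {"n_genes", "exons_per_gene", "exon_bp", "intron_bp",
                  "spacer_bp", "fraction_selected_in_exons"}
_DFE_KEYS = {"beta", "mean_gamma_d", "p_a", "gamma_a"}


def read_simulation_config(path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from a flat ``key = value`` file.

    DFE keys (beta, mean_gamma_d, p_a, gamma_a) and geometry keys may appear
    alongside the population-level keys; unspecified fields keep their
    defaults.
    """
    values = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (part.strip() for part in line.split("=", 1))
            values[key] = val

    def num(key, val):
        return int(val) if key in _CONFIG_INT_KEYS else float(val)

    geom_kw = {k: num(k, v) for k, v in values.items() if k in _GEOMETRY_KEYS}
    dfe_kw = {k: float(v) for k, v in values.items() if k in _DFE_KEYS}
    cfg_kw = {k: num(k, v) for k, v in values.items()
              if k not in _GEOMETRY_KEYS and k not in _DFE_KEYS}
    if geom_kw:
        cfg_kw["geometry"] = ChromosomeGeometry(**geom_kw)
    if dfe_kw:
        cfg_kw["dfe"] = make_dfe(**dfe_kw)
    return SimulationConfig(**cfg_kw)
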