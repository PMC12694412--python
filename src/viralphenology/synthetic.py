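"""Ground-truthed synthetic data with the structure the analyses assume.

The generator emulates a multi-year monthly metagenomic time series of
virus phylotype abundances: a Yule phylogeny on which each lineage's peak
season (phenology) drifts as circular Brownian motion, punctuated by rare
host-switch jumps that reset it; three temporal dynamic classes (annual,
biannual, erratic); "gap" years in which a seasonal population fails to
peak; lognormal multiplicative noise; variable library sizes; unsampled
months; and compositionally biased host/virus genome sequences for
alignment-free host prediction.

Everything is reproducible bit for bit from ``(SimConfig, seed)``.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core_io import AbundanceTable, Sample

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_tree",
    "evolve_phenology",
    "simulate_abundance",
    "simulate_genomes",
    "simulate_dataset",
]

_BASES = "ACGT"


@dataclass
class SimConfig:
    """Study conditions for the synthetic community.

    Defaults describe a five-year monthly series of 50 phylotypes whose
    dynamic-class mix matches the observed shares of annual (17%),
    biannual (2%) and erratic (81%) populations, with peak-to-baseline
    ratio A/b = 10, 30% lognormal noise, ~15% unsampled months and
    occasional gap years.
    """

    n_taxa: int = 50
    n_years: int = 5
    start_year: int = 2000
    birth_rate: float = 1.0  # Yule births per unit time
    sigma2_phenology: float = 1.0  # circular BM rate, months^2 per unit branch
    switch_rate: float = 0.1  # host-switch jumps per unit branch length
    class_probs: tuple[float, float, float] = (0.17, 0.02, 0.81)  # annual, biannual, erratic
    gap_prob: float = 0.1  # P(a year's seasonal peak is skipped)
    amplitude: float = 10.0  # A, seasonal peak height
    baseline: float = 1.0  # b, year-round floor
    kappa: float = 2.0  # peak sharpness of the exponential-cosine bump
    erratic_spikes_per_year: float = 1.0  # Poisson rate of erratic spikes
    noise_sigma: float = 0.3  # sd of lognormal multiplicative noise
    miss_prob: float = 0.15  # P(a month is unsampled)
    library_mu: float = math.log(1e7)  # lognormal log-mean of library reads
    library_sigma: float = 0.5
    n_hosts: int = 5
    amelioration: float = 0.75  # alpha: per-position mixing toward host chain
    genome_length: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        for name in ("birth_rate", "sigma2_phenology", "switch_rate", "gap_prob",
                     "amplitude", "baseline", "kappa", "noise_sigma", "miss_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_months(self) -> int:
        return 12 * self.n_years


@dataclass
class SimTruth:
    """Ground truth recorded by the generator, keyed by taxon id."""

    tree: dendropy.Tree
    phases: dict[str, float]  # peak phase in [0, 12) months
    classes: dict[str, str]  # "annual" | "biannual" | "erratic"
    hosts: dict[str, str]  # taxon -> host id
    branch_jumps: dict[int, int] = field(default_factory=dict)  # edge idx -> jumps

    @property
    def taxa(self) -> list[str]:
        return sorted(self.phases)


def simulate_tree(config: SimConfig) -> dendropy.Tree:
    """Yule pure-birth tree with ``n_taxa`` tips, reproducible from the seed."""
    if config.n_taxa < 2:
        raise ValueError("need n_taxa >= 2")
    from dendropy.simulate import treesim

    rng = random.Random(config.seed)
    # GSA sampling picks a uniform time while the process has exactly n_taxa
    # lineages, so terminal branches get positive lengths.
    tree = treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=0.0,
        num_extant_tips=config.n_taxa,
        gsa_ntax=2 * config.n_taxa,
        rng=rng,
    )
    width = max(4, len(str(config.n_taxa)))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"taxon_{i + 1:0{width}d}"
    return tree


def _wrap12(x: float) -> float:
    return x % 12.0


def evolve_phenology(tree: dendropy.Tree, config: SimConfig) -> SimTruth:
    """Evolve peak phase along the tree: circular BM plus host-switch jumps.

    The root phase is Uniform[0,12).  Each branch of length l adds a
    wrapped-normal increment with variance sigma2_phenology * l; with
    K ~ Poisson(switch_rate * l) jumps the phase is instead resampled
    uniformly (a host switch erases the inherited phenology).  Tips also
    receive a dynamic class (annual/biannual/erratic) and a host label.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sigma2 = config.sigma2_phenology
    lam = config.switch_rate
    branch_jumps: dict[int, int] = {}
    root = tree.seed_node
    root.phase = float(rng.uniform(0, 12))
    for eidx, node in enumerate(tree.preorder_node_iter()):
        if node is root:
            continue
        ell = node.edge.length or 0.0
        phase = node.parent_node.phase
        if sigma2 > 0 and ell > 0:
            phase = _wrap12(phase + rng.normal(0.0, math.sqrt(sigma2 * ell)))
        k = int(rng.poisson(lam * ell)) if lam > 0 and ell > 0 else 0
        if k > 0:
            phase = float(rng.uniform(0, 12))
        branch_jumps[eidx] = k
        node.phase = phase

    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    phases = {leaf.taxon.label: float(leaf.phase) for leaf in tree.leaf_node_iter()}
    class_names = np.array(["annual", "biannual", "erratic"])
    classes = {
        t: str(c) for t, c in zip(labels, rng.choice(class_names, size=len(labels),
                                                     p=list(config.class_probs)))
    }
    host_ids = [f"host_{h + 1}" for h in range(config.n_hosts)]
    hosts = {t: host_ids[int(rng.integers(config.n_hosts))] for t in labels}
    return SimTruth(tree=tree, phases=phases, classes=classes, hosts=hosts,
                    branch_jumps=branch_jumps)


def _seasonal_bump(t: np.ndarray, phase: float, period: float, kappa: float) -> np.ndarray:
    """Exponential-cosine bump, normalized to peak at 1."""
    return np.exp(kappa * (np.cos(2 * np.pi * (t - phase) / period) - 1.0))


def true_signal(taxon: str, truth: SimTruth, config: SimConfig,
                rng: np.random.Generator) -> np.ndarray:
    """Noise-free monthly expectation for one taxon (gap years applied)."""
    t = np.arange(config.n_months, dtype=float)
    b, A, kappa = config.baseline, config.amplitude, config.kappa
    cls = truth.classes[taxon]
    phase = truth.phases[taxon]
    if cls == "erratic":
        signal = np.full(config.n_months, b)
        n_spikes = rng.poisson(config.erratic_spikes_per_year * config.n_years)
        for m in rng.integers(0, config.n_months, size=n_spikes):
            signal[m] += A
        return signal
    period = 12.0 if cls == "annual" else 6.0
    seasonal = A * _seasonal_bump(t, phase, period, kappa)
    gap_years = rng.random(config.n_years) < config.gap_prob
    seasonal[np.repeat(gap_years, 12)] = 0.0  # gap year: baseline only
    return b + seasonal


def simulate_abundance(truth: SimTruth, config: SimConfig) -> AbundanceTable:
    """Observe the true signals through noise, library size and missingness.

    observed = signal * LogNormal(0, noise_sigma) * (library / median library);
    library sizes are lognormal, rounded to integers >= 1; whole months are
    dropped with probability ``miss_prob`` (shared across taxa, as a
    missing sample is missing for every taxon).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    taxa = truth.taxa
    n_m = config.n_months

    libraries = np.maximum(
        1, np.round(rng.lognormal(config.library_mu, config.library_sigma, n_m))
    ).astype(np.int64)
    sampled = rng.random(n_m) >= config.miss_prob
    if sampled.sum() < 2:  # degenerate draw; keep first and last months
        sampled[[0, -1]] = True
    lib_factor = libraries / np.median(libraries[sampled])

    signals = np.vstack([true_signal(t, truth, config, rng) for t in taxa])
    noise = rng.lognormal(0.0, config.noise_sigma, size=signals.shape) \
        if config.noise_sigma > 0 else np.ones_like(signals)
    observed = signals * noise * lib_factor[None, :]

    import datetime as dt

    samples = []
    for m in np.flatnonzero(sampled):
        year, month = config.start_year + m // 12, m % 12 + 1
        samples.append(
            Sample(
                sample_id=f"S{m + 1:03d}",
                date=dt.date(int(year), int(month), 15),
                library_reads=int(libraries[m]),
                fraction="viral",
            )
        )
    return AbundanceTable(taxa=list(taxa), samples=samples,
                          coverage=observed[:, sampled])


def _dirichlet_rows(rng: np.random.Generator, n_states: int) -> np.ndarray:
    return rng.dirichlet(np.ones(4), size=n_states)


def _emit_markov_mixture(
    length: int,
    host_T: np.ndarray,
    global_T: np.ndarray,
    alpha: float,
    rng: np.random.Generator,
) -> str:
    """Emit a sequence from an order-2 chain mixed per position with a global chain."""
    host_cum = np.cumsum(host_T, axis=1)
    glob_cum = np.cumsum(global_T, axis=1)
    u = rng.random(length)
    use_host = rng.random(length) < alpha
    out = np.empty(length, dtype=np.int8)
    out[0] = int(u[0] * 4)
    out[1] = int(u[1] * 4)
    b0, b1 = int(out[0]), int(out[1])
    for i in range(2, length):
        state = b0 * 4 + b1
        row = host_cum[state] if use_host[i] else glob_cum[state]
        ui = u[i]
        b = 0
        while row[b] < ui:
            b += 1
        out[i] = b
        b0, b1 = b1, b
    return "".join(_BASES[c] for c in out)


def simulate_genomes(
    truth: SimTruth, config: SimConfig
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Simulate compositionally biased host and virus genomes.

    Each host gets its own random order-2 Markov chain over {A,C,G,T}
    (Dirichlet-sampled transition rows) and a genome emitted from it.
    Each virus genome is emitted from a per-position mixture: with
    probability ``amelioration`` the next base is drawn from its assigned
    host's chain, otherwise from a shared global chain.  Returns
    (host records, virus records); ground-truth hosts are in ``truth``.
    """
    if config.n_hosts < 2:
        raise ValueError("need n_hosts >= 2")
    if config.genome_length < 1000:
        raise ValueError("genome_length < 1000 is too short for stable k-mer statistics")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    host_ids = [f"host_{h + 1}" for h in range(config.n_hosts)]
    chains = {h: _dirichlet_rows(rng, 16) for h in host_ids}
    global_chain = _dirichlet_rows(rng, 16)

    hosts = [
        SeqRecord(
            Seq(_emit_markov_mixture(config.genome_length, chains[h], chains[h], 1.0, rng)),
            id=h, description="synthetic host genome",
        )
        for h in host_ids
    ]
    viruses = [
        SeqRecord(
            Seq(
                _emit_markov_mixture(
                    config.genome_length, chains[truth.hosts[t]], global_chain,
                    config.amelioration, rng,
                )
            ),
            id=t, description=f"synthetic virus genome (true host {truth.hosts[t]})",
        )
        for t in truth.taxa
    ]
    return hosts, viruses


def simulate_dataset(config: SimConfig, genomes: bool = False):
    """Convenience wrapper: tree -> phenology -> abundance (-> genomes).

    Returns (truth, table) or (truth, table, hosts, viruses).
    """
    tree = simulate_tree(config)
    truth = evolve_phenology(tree, config)
    table = simulate_abundance(truth, config)
    if not genomes:
        return truth, table
    hosts, viruses = simulate_genomes(truth, config)
    return truth, table, hosts, viruses
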