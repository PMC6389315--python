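"""Forward Wright-Fisher simulation of nonrecombining chromosome length.

A population of N haploid individuals each carries one nonrecombining
chromosome: a length in bp plus a set of intact functional elements.
Each generation, N offspring choose parents with probability proportional
to fitness, then mutate: Poisson numbers of insertion, deletion and
(optional) ectopic-deletion events per chromosome, each with a uniform
position and a size drawn from its distribution.  Insertions add neutral
DNA; an insertion landing inside an intact element disrupts it at cost
``s_ins``.  A deletion removes its span, disrupting every intact element it
touches at cost ``s_del`` each.  Fitness is multiplicative over incurred
disruptions, ``(1-s_ins)^a * (1-s_del)^b``, so an untouched chromosome has
fitness 1 and a disrupted element costs nothing on further hits.

Three regimes follow from the cost structure:

* expansion — deletions cost more than insertions while intact elements are
  dense, so insertions fix faster and mean length grows;
* drift — with no intact elements (or equal zero costs) and equal
  insertion/deletion rates and sizes, length performs an unbiased walk;
* shrinkage — an ectopic channel of rare large deletions with little
  remaining functional content drives mean length down.

Event rates are per chromosome per generation by default (length-
independent); a per-bp mode scales them by current length / initial length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "SizeDist",
    "SimConfig",
    "Chromosome",
    "SimTrajectory",
    "new_chromosome",
    "mutate",
    "fitness",
    "next_generation",
    "run_replicate",
    "run_scenario",
    "scenario_config",
    "SCENARIOS",
]

MIN_LENGTH_BP = 1000  # chromosomes are floored here; the event is clipped


@dataclass(frozen=True)
class SizeDist:
    """Event-size distribution over bp: fixed, exponential or log-uniform."""

    kind: str = "exponential"
    a: float = 5000.0  # fixed value / exponential mean / log-uniform low
    b: float = 0.0  # log-uniform high

    def draw(self, rng: np.random.Generator) -> int:
        if self.kind == "fixed":
            return max(1, int(round(self.a)))
        if self.kind == "exponential":
            return max(1, int(round(rng.exponential(self.a))))
        if self.kind == "loguniform":
            return max(1, int(round(np.exp(rng.uniform(np.log(self.a), np.log(self.b))))))
        raise ValueError(f"unknown size distribution {self.kind!r}")


@dataclass(frozen=True)
class SimConfig:
    N: int = 200  # haploid population size
    T: int = 2000  # generations
    L0: int = 1_000_000  # initial chromosome length, bp
    F0: int = 0  # initial intact functional elements
    element_bp: int = 5000  # extent of each element
    mu_ins: float = 0.1  # insertion events / chromosome / generation
    mu_del: float = 0.1
    ins_size: SizeDist = field(default_factory=SizeDist)
    del_size: SizeDist = field(default_factory=SizeDist)
    s_ins: float = 0.0  # cost of disrupting an element by insertion
    s_del: float = 0.0  # cost per element disrupted by deletion
    ectopic_rate: float = 0.0  # rare large-deletion channel
    ectopic_size: SizeDist = field(default_factory=lambda: SizeDist("exponential", 20000.0))
    rate_per_bp: bool = False  # scale event rates by length/L0
    replicates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if min(self.mu_ins, self.mu_del, self.ectopic_rate) < 0:
            raise ValueError("rates must be non-negative")
        for s in (self.s_ins, self.s_del):
            if not 0 <= s < 1:
                raise ValueError("fitness costs must be in [0, 1)")
        if self.F0 * self.element_bp > self.L0:
            raise ValueError("functional elements exceed chromosome length")


@dataclass(frozen=True)
class Chromosome:
    """Immutable chromosome state; offspring share the parent object
    unless mutated (copy-on-write), which keeps large populations cheap."""

    length: int
    elements: tuple[tuple[int, int], ...]  # intact elements, [start, end)
    disrupted_ins: int = 0  # elements lost to insertions (lineage total)
    disrupted_del: int = 0  # elements lost to deletions
    sum_ins: int = 0  # cumulative applied insertion bp
    sum_del: int = 0  # cumulative applied deletion bp
    fitness: float = 1.0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be positive")
        for (s, e) in self.elements:
            if not 0 <= s < e <= self.length:
                raise ValueError("element outside chromosome")
        if not 0 < self.fitness <= 1:
            raise ValueError("fitness must be in (0, 1]")


def new_chromosome(config: SimConfig) -> Chromosome:
    """Chromosome with F0 evenly spaced intact elements and fitness 1."""
    if config.F0 == 0:
        return Chromosome(length=config.L0, elements=())
    gap = config.L0 / config.F0
    els = []
    for i in range(config.F0):
        s = int(round(i * gap))
        e = min(s + config.element_bp, config.L0)
        els.append((s, e))
    return Chromosome(length=config.L0, elements=tuple(els))


def fitness(chrom: Chromosome, config: SimConfig) -> float:
    """Multiplicative fitness from scratch: (1-s_ins)^a * (1-s_del)^b."""
    return (1 - config.s_ins) ** chrom.disrupted_ins * (
        1 - config.s_del
    ) ** chrom.disrupted_del


def _apply_insertion(
    chrom: Chromosome, pos: int, size: int, config: SimConfig
) -> Chromosome:
    els = []
    hit = 0
    for (s, e) in chrom.elements:
        if s >= pos:
            els.append((s + size, e + size))
        elif pos < e:  # insertion lands inside the element: disrupted
            hit += 1
        else:
            els.append((s, e))
    f = chrom.fitness * (1 - config.s_ins) ** hit
    return Chromosome(
        length=chrom.length + size,
        elements=tuple(els),
        disrupted_ins=chrom.disrupted_ins + hit,
        disrupted_del=chrom.disrupted_del,
        sum_ins=chrom.sum_ins + size,
        sum_del=chrom.sum_del,
        fitness=f,
    )


def _apply_deletion(
    chrom: Chromosome, start: int, size: int, config: SimConfig
) -> tuple[Chromosome, int]:
    """Returns the mutated chromosome and the applied (possibly clipped) bp."""
    end = min(start + size, chrom.length)
    applied = end - start
    if chrom.length - applied < MIN_LENGTH_BP:
        applied = max(0, chrom.length - MIN_LENGTH_BP)
        end = start + applied
    if applied == 0:
        return chrom, 0
    els = []
    hit = 0
    for (s, e) in chrom.elements:
        if e <= start:
            els.append((s, e))
        elif s >= end:
            els.append((s - applied, e - applied))
        else:
            hit += 1  # removed or truncated: disrupted either way
    f = chrom.fitness * (1 - config.s_del) ** hit
    return (
        Chromosome(
            length=chrom.length - applied,
            elements=tuple(els),
            disrupted_ins=chrom.disrupted_ins,
            disrupted_del=chrom.disrupted_del + hit,
            sum_ins=chrom.sum_ins,
            sum_del=chrom.sum_del + applied,
            fitness=f,
        ),
        applied,
    )


def mutate(
    chrom: Chromosome,
    config: SimConfig,
    rng: np.random.Generator,
    n_ins: int | None = None,
    n_del: int | None = None,
    n_ect: int | None = None,
    event_log: list | None = None,
) -> Chromosome:
    """Apply Poisson numbers of insertion/deletion/ectopic events.

    Explicit counts override the Poisson draws (used by tests to force
    events).  Each event draws a uniform position and a size from its
    distribution; the length update is exact and appended to ``event_log``
    as ``(type, applied_bp)`` when a log is supplied.
    """
    scale = chrom.length / config.L0 if config.rate_per_bp else 1.0
    if n_ins is None:
        n_ins = rng.poisson(config.mu_ins * scale)
    if n_del is None:
        n_del = rng.poisson(config.mu_del * scale)
    if n_ect is None:
        n_ect = rng.poisson(config.ectopic_rate * scale) if config.ectopic_rate else 0

    kinds = ["I"] * n_ins + ["D"] * n_del + ["E"] * n_ect
    if len(kinds) > 1:
        rng.shuffle(kinds)
    for kind in kinds:
        if kind == "I":
            size = config.ins_size.draw(rng)
            pos = int(rng.integers(0, chrom.length + 1))
            chrom = _apply_insertion(chrom, pos, size, config)
            if event_log is not None:
                event_log.append(("INS", size))
        else:
            dist = config.del_size if kind == "D" else config.ectopic_size
            size = dist.draw(rng)
            start = int(rng.integers(0, chrom.length))
            chrom, applied = _apply_deletion(chrom, start, size, config)
            if event_log is not None:
                event_log.append(("DEL", applied))
    return chrom


def next_generation(
    pop: list[Chromosome],
    config: SimConfig,
    rng: np.random.Generator,
    event_log: list | None = None,
) -> list[Chromosome]:
    """One Wright-Fisher step: fitness-proportional parents, then mutation."""
    N = len(pop)
    w = np.fromiter((c.fitness for c in pop), dtype=float, count=N)
    parents = rng.choice(N, size=N, p=w / w.sum())
    scale = (
        np.fromiter((pop[i].length for i in parents), dtype=float, count=N) / config.L0
        if config.rate_per_bp
        else np.ones(N)
    )
    n_ins = rng.poisson(config.mu_ins * scale)
    n_del = rng.poisson(config.mu_del * scale)
    n_ect = (
        rng.poisson(config.ectopic_rate * scale)
        if config.ectopic_rate
        else np.zeros(N, dtype=int)
    )
    out = []
    for i in range(N):
        c = pop[parents[i]]
        if n_ins[i] or n_del[i] or n_ect[i]:
            c = mutate(
                c, config, rng,
                n_ins=int(n_ins[i]), n_del=int(n_del[i]), n_ect=int(n_ect[i]),
                event_log=event_log,
            )
        out.append(c)
    return out


@dataclass(frozen=True)
class SimTrajectory:
    """Per-generation population summaries plus per-replicate finals."""

    mean_length: np.ndarray  # (replicates, T+1)
    median_length: np.ndarray
    mean_intact: np.ndarray
    mean_fitness: np.ndarray
    final_lengths: np.ndarray  # per-replicate mean final length
    L0: int

    @property
    def mean_final_change(self) -> float:
        return float(np.mean(self.final_lengths) - self.L0)

    def sign_test(self, alternative: str = "two-sided") -> float:
        """Sign test of replicate-mean final length vs L0."""
        k = int(np.sum(self.final_lengths > self.L0))
        n = int(np.sum(self.final_lengths != self.L0))
        if n == 0:
            return 1.0
        return float(stats.binomtest(k, n, 0.5, alternative=alternative).pvalue)


def run_replicate(
    config: SimConfig, rng: np.random.Generator, event_log: list | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[Chromosome]]:
    """One replicate; returns per-generation stat arrays and the final pop."""
    pop = [new_chromosome(config)] * config.N
    T = config.T
    mean_len = np.empty(T + 1)
    med_len = np.empty(T + 1)
    mean_int = np.empty(T + 1)
    mean_fit = np.empty(T + 1)

    def record(t: int) -> None:
        lens = np.fromiter((c.length for c in pop), dtype=float, count=config.N)
        mean_len[t] = lens.mean()
        med_len[t] = np.median(lens)
        mean_int[t] = np.mean([len(c.elements) for c in pop])
        mean_fit[t] = np.mean([c.fitness for c in pop])

    record(0)
    for t in range(1, T + 1):
        pop = next_generation(pop, config, rng, event_log)
        record(t)
    return mean_len, med_len, mean_int, mean_fit, pop


def run_scenario(config: SimConfig, check_replay: bool = True) -> SimTrajectory:
    """Run ``config.replicates`` independent replicates.

    ``check_replay`` verifies the exact length bookkeeping of every final
    chromosome against its cumulative event sums (replay identity).
    """
    R, T = config.replicates, config.T
    mean_len = np.empty((R, T + 1))
    med_len = np.empty((R, T + 1))
    mean_int = np.empty((R, T + 1))
    mean_fit = np.empty((R, T + 1))
    finals = np.empty(R)
    seeds = np.random.SeedSequence(config.seed).spawn(R)
    for r in range(R):
        rng = np.random.default_rng(seeds[r])
        ml, md, mi, mf, pop = run_replicate(config, rng)
        mean_len[r], med_len[r], mean_int[r], mean_fit[r] = ml, md, mi, mf
        finals[r] = ml[-1]
        if check_replay:
            for c in pop:
                assert c.length == config.L0 + c.sum_ins - c.sum_del, (
                    "length bookkeeping violated"
                )
    return SimTrajectory(
        mean_length=mean_len,
        median_length=med_len,
        mean_intact=mean_int,
        mean_fitness=mean_fit,
        final_lengths=finals,
        L0=config.L0,
    )


def scenario_config(scenario: str, **overrides) -> SimConfig:
    """Preset configuration for one of the three qualitative regimes."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    base = SCENARIOS[scenario]
    return replace(base, **overrides)


SCENARIOS: dict[str, SimConfig] = {
    # deletions costly while functional elements are dense: length grows
    "expansion": SimConfig(
        N=200, T=2000, L0=1_000_000, F0=120, element_bp=5000,
        mu_ins=0.1, mu_del=0.1,
        ins_size=SizeDist("exponential", 5000.0),
        del_size=SizeDist("exponential", 5000.0),
        s_ins=0.005, s_del=0.05,
        replicates=20,
    ),
    # no functional elements, symmetric rates and sizes: unbiased walk
    "drift": SimConfig(
        N=200, T=2000, L0=1_000_000, F0=0,
        mu_ins=0.1, mu_del=0.1,
        ins_size=SizeDist("exponential", 5000.0),
        del_size=SizeDist("exponential", 5000.0),
        replicates=50,
    ),
    # rare large ectopic deletions with no functional content: length falls
    "shrinkage": SimConfig(
        N=200, T=1000, L0=1_000_000, F0=0,
        mu_ins=0.1, mu_del=0.1,
        ins_size=SizeDist("exponential", 5000.0),
        del_size=SizeDist("exponential", 5000.0),
        ectopic_rate=0.02,
        ectopic_size=SizeDist("exponential", 20000.0),
        replicates=20,
    ),
}
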