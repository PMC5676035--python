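"""Simulation of a haploid hybrid cross and pooled-segregant sequencing.

Emulates the experimental design of pooled-segregant QTL mapping in
*Saccharomyces cerevisiae*: two haploid parents (labelled A and B)
differing at a dense set of biallelic SNPs are crossed, the F1 hybrid is
sporulated, and a few hundred haploid segregants are phenotyped.  A pool
of superior segregants (truncation-selected on the trait) and a pool of
random segregants are then sequenced; per-site read counts for the two
parental alleles carry the linkage signal.

Meiosis uses the Haldane (no-interference) model: the number of
crossovers per chromosome is Poisson with mean equal to the genetic
length in Morgans, and crossover positions are uniform on the genetic
map.  Phenotypes combine a baseline trait level with per-QTL fractional
effects (multiplicative by default) and multiplicative log-normal noise.
Pool sequencing draws per-site depth from a Poisson and parent-A read
counts from a binomial (optionally beta-binomial) around the true pool
allele fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from bsaqtl.poolfreq import PoolCounts

__all__ = [
    "Chromosome", "GenomeMap", "QtlEffect", "PhenotypeModel", "Segregant",
    "PoolSpec", "simulate_meiosis", "assign_phenotypes", "select_pools",
    "sample_pool_reads",
]

#: Physical lengths (bp) of the 16 S. cerevisiae chromosomes (S288c, rounded
#: to the nearest kb), used by :meth:`GenomeMap.full_yeast`.
_YEAST_CHROM_KB = [230, 813, 317, 1532, 577, 270, 1091, 563,
                   440, 746, 667, 1078, 924, 784, 1091, 948]

#: Roman-numeral chromosome names in karyotype order.
_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII",
          "IX", "X", "XI", "XII", "XIII", "XIV", "XV", "XVI"]


@dataclass(frozen=True)
class Chromosome:
    """One chromosome of the cross: name, physical and genetic length."""

    name: str
    length_bp: int
    morgans: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name}: length_bp must be > 0")
        if self.morgans < 0:
            raise ValueError(f"chromosome {self.name}: genetic length must be >= 0")


@dataclass(frozen=True)
class GenomeMap:
    """Marker map of the cross.

    Parameters
    ----------
    chromosomes
        Ordered chromosomes with physical (bp) and genetic (Morgan) lengths.
    snp_positions
        Per-chromosome sorted, strictly increasing 1-based SNP positions.
    allele_labels
        Optional per-chromosome list of (parentA base, parentB base) pairs,
        one per SNP; generated deterministically when omitted.
    """

    chromosomes: tuple[Chromosome, ...]
    snp_positions: dict[str, np.ndarray]
    allele_labels: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome map has no chromosomes")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for chrom in self.chromosomes:
            pos = np.asarray(self.snp_positions.get(chrom.name, ()), dtype=np.int64)
            if pos.size and not np.all(np.diff(pos) > 0):
                raise ValueError(f"SNP positions on {chrom.name} not strictly increasing")
            object.__setattr__(self, "snp_positions",
                               {**self.snp_positions, chrom.name: pos})
        for name, labels in self.allele_labels.items():
            for a, b in labels:
                if a == b:
                    raise ValueError(f"SNP on {name} with identical parent alleles {a!r}")

    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def n_snps(self) -> int:
        return int(sum(self.snp_positions[c.name].size for c in self.chromosomes))

    def alleles(self, chrom: str) -> list[tuple[str, str]]:
        """Parent (A, B) bases per SNP; a fixed A/G convention if unset."""
        if chrom in self.allele_labels:
            return self.allele_labels[chrom]
        return [("A", "G")] * self.snp_positions[chrom].size

    def snp_index(self, chrom: str, pos: int) -> int:
        """Index of the SNP at an exact position; raises if absent."""
        positions = self.snp_positions[chrom]
        i = int(np.searchsorted(positions, pos))
        if i >= positions.size or positions[i] != pos:
            raise KeyError(f"no SNP at {chrom}:{pos}")
        return i

    @classmethod
    def regular(cls, n_chromosomes: int = 4, length_bp: int = 500_000,
                snp_spacing: int = 2_000, morgans: float = 1.0,
                prefix: str = "chr") -> "GenomeMap":
        """Evenly spaced test-scale map (default 4 x 500 kb, 1 SNP / 2 kb)."""
        chroms = tuple(
            Chromosome(f"{prefix}{_ROMAN[i]}" if i < 16 else f"{prefix}{i + 1}",
                       length_bp, morgans)
            for i in range(n_chromosomes)
        )
        positions = {c.name: np.arange(snp_spacing, length_bp + 1, snp_spacing,
                                       dtype=np.int64)
                     for c in chroms}
        return cls(chroms, positions)

    @classmethod
    def full_yeast(cls, snp_spacing: int = 3_000,
                   morgans_per_kb: float = 1.0 / 300.0) -> "GenomeMap":
        """16-chromosome yeast-scale map.

        Default density of one parent-differentiating SNP per 3 kb and a
        generic ~0.33 cM/kb yeast recombination rate.
        """
        chroms = tuple(
            Chromosome(f"chr{_ROMAN[i]}", kb * 1000, kb * morgans_per_kb)
            for i, kb in enumerate(_YEAST_CHROM_KB)
        )
        positions = {c.name: np.arange(snp_spacing, c.length_bp + 1, snp_spacing,
                                       dtype=np.int64)
                     for c in chroms}
        return cls(chroms, positions)


@dataclass(frozen=True)
class QtlEffect:
    """One planted QTL: locus, which parent's allele is favoured, effect size.

    ``effect`` is fractional (+0.35 means carriers of the favoured allele
    produce 35 % more trait).  ``dominant`` is carried for completeness of
    the model description; segregants of this cross are haploid, so it
    does not enter the haploid simulation.
    """

    chrom: str
    pos: int
    favored_parent: str  # "A" or "B"
    effect: float
    dominant: bool = False

    def __post_init__(self) -> None:
        if self.effect <= -1:
            raise ValueError("fractional effect must be > -1")
        if self.favored_parent not in ("A", "B"):
            raise ValueError("favored_parent must be 'A' or 'B'")


@dataclass(frozen=True)
class PhenotypeModel:
    """Trait model: baseline level, QTL effects, and environmental noise.

    ``baseline`` is the trait value (ppm) of a segregant carrying no
    favoured allele.  ``noise_cv`` is the coefficient of variation of
    multiplicative log-normal noise with unit mean.  ``combine_rule`` is
    ``"multiplicative"`` (effects compose as products, i.e. additive on
    the log scale) or ``"additive"`` (additive on the level).
    """

    baseline: float = 1.0
    qtl_effects: tuple[QtlEffect, ...] = ()
    noise_cv: float = 0.0
    combine_rule: str = "multiplicative"

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.combine_rule not in ("multiplicative", "additive"):
            raise ValueError("combine_rule must be 'multiplicative' or 'additive'")


@dataclass(frozen=True)
class Segregant:
    """A haploid F1 segregant.

    ``haplotype`` maps chromosome name to a uint8 array over that
    chromosome's SNPs: 0 = parent-A origin, 1 = parent-B origin.
    """

    id: int
    haplotype: dict[str, np.ndarray]
    phenotype: float | None = None

    def origin(self, chrom: str, snp_index: int) -> str:
        return "A" if self.haplotype[chrom][snp_index] == 0 else "B"


@dataclass(frozen=True)
class PoolSpec:
    """A sequencing pool: member segregant ids plus the depth model."""

    members: tuple[int, ...]
    label: str  # "superior" or "random"
    target_coverage: float = 100.0
    overdispersion: float = 0.0  # beta-binomial rho; 0 = pure binomial

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("pool has no members")
        if self.target_coverage <= 0:
            raise ValueError("target_coverage must be > 0")
        if not 0 <= self.overdispersion < 1:
            raise ValueError("overdispersion must lie in [0, 1)")


def simulate_meiosis(gmap: GenomeMap, n_segregants: int,
                     seed: int | np.random.Generator = 0) -> list[Segregant]:
    """Draw haploid segregant haplotypes under the Haldane model.

    Per chromosome and gamete: crossover count ~ Poisson(genetic length
    in Morgans), crossover positions uniform on the genetic map (uniform
    in bp, since the per-chromosome recombination rate is constant), and
    the parental origin at the left telomere is a fair coin.  The origin
    at each SNP then flips at every crossover to its left.
    """
    if n_segregants < 1:
        raise ValueError("n_segregants must be >= 1")
    if gmap.n_snps == 0:
        raise ValueError("genome map carries no SNPs")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    haplos: list[dict[str, np.ndarray]] = [dict() for _ in range(n_segregants)]
    for chrom in gmap.chromosomes:
        positions = gmap.snp_positions[chrom.name]
        n_xo = rng.poisson(chrom.morgans, size=n_segregants)
        starts = rng.integers(0, 2, size=n_segregants, dtype=np.uint8)
        for i in range(n_segregants):
            xo = np.sort(rng.uniform(0, chrom.length_bp, size=n_xo[i]))
            flips = np.searchsorted(xo, positions).astype(np.int64)
            haplos[i][chrom.name] = ((starts[i] + flips) % 2).astype(np.uint8)
    return [Segregant(id=i, haplotype=h) for i, h in enumerate(haplos)]


def _carrier_indicator(seg: Segregant, gmap: GenomeMap, qtl: QtlEffect) -> bool:
    idx = gmap.snp_index(qtl.chrom, qtl.pos)
    return seg.origin(qtl.chrom, idx) == qtl.favored_parent


def assign_phenotypes(segregants: list[Segregant], model: PhenotypeModel,
                      gmap: GenomeMap,
                      seed: int | np.random.Generator = 0) -> list[Segregant]:
    """Attach trait values to segregants under the phenotype model.

    Multiplicative rule: value = baseline * prod(1 + effect_i) over carried
    favoured alleles, times unit-mean log-normal noise with CV ``noise_cv``.
    Additive rule replaces the product with 1 + sum(effect_i).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for qtl in model.qtl_effects:
        gmap.snp_index(qtl.chrom, qtl.pos)  # validate positions up front

    if model.noise_cv > 0:
        sigma2 = np.log1p(model.noise_cv ** 2)
        noise = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2),
                              size=len(segregants))
    else:
        noise = np.ones(len(segregants))

    out = []
    for seg, eps in zip(segregants, noise):
        carried = [q.effect for q in model.qtl_effects
                   if _carrier_indicator(seg, gmap, q)]
        if model.combine_rule == "multiplicative":
            genetic = float(np.prod([1 + e for e in carried])) if carried else 1.0
        else:
            genetic = 1.0 + float(np.sum(carried)) if carried else 1.0
        out.append(replace(seg, phenotype=model.baseline * genetic * float(eps)))
    return out


def select_pools(segregants: list[Segregant], pool_size: int = 24,
                 cutoff: float | None = None, top_k: int | None = None,
                 seed: int | np.random.Generator = 0,
                 target_coverage: float = 100.0,
                 overdispersion: float = 0.0) -> tuple[PoolSpec, PoolSpec]:
    """Build the superior (truncation-selected) and random pools.

    Selection is either by trait cutoff (every member's phenotype >=
    ``cutoff``; a random ``pool_size``-subset of qualifiers is taken) or by
    ``top_k`` (the ``top_k`` largest phenotypes, ties broken by segregant
    id).  The random pool is a uniform sample without replacement from
    all segregants.
    """
    if (cutoff is None) == (top_k is None):
        raise ValueError("specify exactly one of cutoff or top_k")
    if any(s.phenotype is None for s in segregants):
        raise ValueError("segregants lack phenotypes; run assign_phenotypes first")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    if cutoff is not None:
        qualifiers = [s.id for s in segregants if s.phenotype >= cutoff]
        if len(qualifiers) < pool_size:
            raise ValueError(
                f"only {len(qualifiers)} segregants reach cutoff {cutoff}, "
                f"need {pool_size} (shortfall {pool_size - len(qualifiers)})")
        chosen = rng.choice(np.asarray(qualifiers), size=pool_size, replace=False)
        superior = tuple(int(i) for i in np.sort(chosen))
    else:
        order = sorted(segregants, key=lambda s: (-s.phenotype, s.id))
        superior = tuple(sorted(s.id for s in order[:top_k]))

    all_ids = np.asarray([s.id for s in segregants])
    rand = rng.choice(all_ids, size=pool_size, replace=False)
    random_pool = tuple(int(i) for i in np.sort(rand))

    return (PoolSpec(superior, "superior", target_coverage, overdispersion),
            PoolSpec(random_pool, "random", target_coverage, overdispersion))


def pool_allele_fractions(pool: PoolSpec, segregants: list[Segregant],
                          gmap: GenomeMap) -> dict[str, np.ndarray]:
    """True per-SNP fraction of pool members carrying the parent-A allele."""
    by_id = {s.id: s for s in segregants}
    members = [by_id[i] for i in pool.members]
    out = {}
    for chrom in gmap.chrom_names:
        H = np.stack([m.haplotype[chrom] for m in members])
        out[chrom] = 1.0 - H.mean(axis=0)  # origin 0 == parent A
    return out


def sample_pool_reads(pool: PoolSpec, segregants: list[Segregant],
                      gmap: GenomeMap,
                      seed: int | np.random.Generator = 0) -> list[PoolCounts]:
    """Simulate pooled sequencing read counts at every SNP.

    Depth ~ Poisson(target_coverage); parent-A reads ~ Binomial(depth, f)
    with f the true pool allele fraction, or Beta-Binomial when
    ``pool.overdispersion`` (rho) is positive — the per-site success
    probability is then Beta-distributed around f with intraclass
    correlation rho, emulating unequal DNA contributions of pool members.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fractions = pool_allele_fractions(pool, segregants, gmap)
    counts: list[PoolCounts] = []
    for chrom in gmap.chrom_names:
        positions = gmap.snp_positions[chrom]
        f = fractions[chrom]
        depth = rng.poisson(pool.target_coverage, size=f.size)
        if pool.overdispersion > 0:
            rho = pool.overdispersion
            conc = (1 - rho) / rho
            a = np.clip(f * conc, 1e-12, None)
            b = np.clip((1 - f) * conc, 1e-12, None)
            p = np.where(f <= 0, 0.0, np.where(f >= 1, 1.0, rng.beta(a, b)))
        else:
            p = f
        k = rng.binomial(depth, p)
        counts.extend(
            PoolCounts(chrom, int(pos), int(ka), int(d - ka))
            for pos, d, ka in zip(positions, depth, k)
        )
    return counts
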