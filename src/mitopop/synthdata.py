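"""Synthetic inputs: a fixed 35-sample variant-profile fixture and a
seeded simulator of serial founder effects.

The fixture encodes the published per-sample variant descriptions of a
35-animal Nguni herd on the T1 subhaplogroup system: every sample
carries the T1 control-region transitions 16050 and 16113 and a
single-base insertion at 16201 (allele G in three animals, A in the
rest); three T1b members lack 16255 (reversions); four T1b1 members
additionally carry the T1c transition 16122 and the 14523 A>T
transversion; one T1b member lacks the T1b1 transition 16022; and one
sample each sits in T1, T1c and T1d. Private control-region transitions
at fixed positions make haplotype condensation non-trivial. The private
placement is invented (the per-sample descriptions do not enumerate
private variants) and is labelled as such wherever it is exported.

The simulator embodies the serial-founder hypothesis those data were
used to test: a chain of populations, each founded by a small sample of
the previous one, evolving under haploid Wright-Fisher drift (mtDNA is
maternally inherited and effectively haploid) with transition-biased
per-site mutation. At the default settings diversity decreases, and
differentiation from the chain head increases, along the chain.

Because the real reference genome cannot ship with the package, a
deterministic synthetic stand-in of the same length is generated, with
the transversion-defining site pinned so diagnostic motifs stay valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .haplotyper import HaplogroupNode, HaplogroupTree, MotifSite, default_tree
from .popgen import PopulationSet
from .refvar import (
    DELETION,
    INSERTION,
    PURINES,
    SUBSTITUTION,
    TRANSITION_PARTNER,
    ReferenceGenome,
    Variant,
    VariantProfile,
    profile_from_site_list,
)

#: Length of the bovine mitochondrial reference coordinate system.
BRS_LENGTH = 16338

# Fixed seed for the synthetic reference sequence: every run and every
# genome length derives the same stand-in reference.
_REFERENCE_SEED = 715225739

# Sites whose reference base is pinned so that explicit-allele motifs
# (the 14523 A>T transversion) remain valid on the synthetic reference.
_ANCHOR_BASES = {14523: "A"}


def scale_position(position: int, length: int) -> int:
    """Map a BRS coordinate onto a shorter synthetic genome, proportionally."""
    if length == BRS_LENGTH:
        return position
    return max(1, round(position * length / BRS_LENGTH))


def synthetic_reference(length: int = BRS_LENGTH) -> ReferenceGenome:
    """A deterministic synthetic stand-in for the bovine reference.

    The sequence is random (it is *not* the real reference genome); only
    the coordinate system and the anchor bases needed by the diagnostic
    motifs mimic BRS numbering.
    """
    rng = np.random.default_rng(_REFERENCE_SEED)
    bases = np.array(list("ACGT"))
    arr = bases[rng.integers(4, size=length)]
    for pos, base in _ANCHOR_BASES.items():
        arr[scale_position(pos, length) - 1] = base
    return ReferenceGenome(
        id=f"synthetic-bovine-mt-{length}", sequence="".join(arr), circular=True
    )


def scaled_haplogroup_tree(length: int, tree: HaplogroupTree | None = None) -> HaplogroupTree:
    """Remap every motif position of a tree onto a shorter genome."""
    tree = tree or default_tree()
    if length == BRS_LENGTH:
        return tree
    nodes = []
    for node in tree.nodes.values():
        motif = tuple(
            MotifSite(scale_position(m.position, length), m.change, m.placeholder)
            for m in node.motif
        )
        nodes.append(HaplogroupNode(node.name, node.parent, motif))
    scaled = HaplogroupTree(nodes)
    positions = [m.position for n in scaled.nodes.values() for m in n.motif]
    if len(positions) != len(set(positions)):
        raise ValueError(f"genome length {length} collapses diagnostic positions")
    return scaled


# ---------------------------------------------------------------------------
# Applying variants to a reference (inverse of alignment extraction)
# ---------------------------------------------------------------------------

def mutate(reference: ReferenceGenome, variant_set: Sequence[Variant]) -> str:
    """Apply variants to the reference, producing a sample sequence.

    Variants are applied right-to-left so that every position stays a
    reference coordinate regardless of upstream indels. Overlapping
    variants (two edits claiming the same reference base, or two
    insertions at one anchor) are rejected.
    """
    occupied: set[tuple] = set()
    for v in variant_set:
        if v.kind == SUBSTITUTION:
            span = {(v.position, "base")}
        elif v.kind == DELETION:
            span = {(p, "base") for p in range(v.position, v.position + len(v.ref_allele))}
        else:
            span = {(v.position, "ins")}
        if span & occupied:
            raise ValueError(f"overlapping variants at position {v.position}")
        occupied |= span
        end = v.position + max(len(v.ref_allele), 1) - 1
        if not 1 <= v.position <= len(reference) or end > len(reference):
            raise ValueError(f"variant at {v.position} outside reference")

    seq = list(reference.sequence)
    for v in sorted(variant_set, key=lambda v: v.sort_key, reverse=True):
        i = v.position - 1
        if v.kind == SUBSTITUTION:
            if seq[i] != v.ref_allele:
                raise ValueError(
                    f"reference base at {v.position} is {seq[i]}, variant says "
                    f"{v.ref_allele}"
                )
            seq[i] = v.alt_allele
        elif v.kind == INSERTION:
            seq[i + 1 : i + 1] = list(v.alt_allele)
        else:  # deletion
            if "".join(seq[i : i + len(v.ref_allele)]) != v.ref_allele:
                raise ValueError(f"deletion alleles at {v.position} do not match reference")
            del seq[i : i + len(v.ref_allele)]
    return "".join(seq)


# ---------------------------------------------------------------------------
# The 35-sample fixture
# ---------------------------------------------------------------------------

#: Sample ids, matching the numbering used in the published per-sample
#: descriptions (34 consecutive animals plus number 40).
FIXTURE_SAMPLE_IDS: tuple[str, ...] = tuple(str(i) for i in range(1, 35)) + ("40",)

_NO_16255 = {"6", "7", "8"}          # T1b members lacking 16255 (reversions)
_NOT_T1B = {"16", "27", "40"}        # the three samples outside T1b
_NO_16022 = {"28"}                   # the T1b member outside T1b1
_WITH_14523 = {"4", "24", "26", "32"}  # carry T1b + T1c markers + 14523 A>T
_G_INSERTION = {"6", "10", "15"}     # G allele of the 16201 insertion

#: Private control-region transitions (position per sample). The
#: placement is invented — fixed, non-random positions in the variable
#: 15900-16300 window, clear of every diagnostic site — and exists so
#: that haplotype condensation on the fixture is non-trivial (samples 5
#: and 13 deliberately share one, giving a multiplicity-2 haplotype).
DEFAULT_PRIVATE_SITES: dict[str, tuple[int, ...]] = {
    "3": (15917,),
    "5": (15941,),
    "13": (15941,),
    "11": (15959,),
    "19": (15973,),
    "23": (15994,),
    "31": (16007,),
}


def generate_nguni_fixture(
    reference: ReferenceGenome | None = None,
    tree: HaplogroupTree | None = None,
    private_sites: dict[str, tuple[int, ...]] | None = None,
) -> list[VariantProfile]:
    """Build the deterministic 35-profile herd fixture (population "Nguni").

    Samples not singled out by the per-sample descriptions carry the
    generic T1b1 motif {16050, 16113, 16255, 7542, 16022} plus the 16201
    insertion. The defining site for T1d is taken from the haplogroup
    config (a placeholder slot there).
    """
    reference = reference or synthetic_reference()
    tree = tree or default_tree()
    private_sites = DEFAULT_PRIVATE_SITES if private_sites is None else private_sites
    t1d_site = tree.nodes["T1d"].motif[0].position

    profiles = []
    for sid in FIXTURE_SAMPLE_IDS:
        sites: list[tuple[int, str]] = [(16050, "Ts"), (16113, "Ts")]
        if sid not in _NO_16255:
            sites.append((16255, "Ts"))
        if sid not in _NOT_T1B:
            sites.append((7542, "Ts"))
            if sid not in _NO_16022:
                sites.append((16022, "Ts"))
        if sid in _WITH_14523:
            sites.append((16122, "Ts"))
            sites.append((14523, "AT"))
        if sid == "16":
            sites.append((16122, "Ts"))
        if sid == "27":
            sites.append((t1d_site, "Ts"))
        sites.append((16201, "+G" if sid in _G_INSERTION else "+A"))
        for pos in private_sites.get(sid, ()):
            sites.append((pos, "Ts"))
        profiles.append(profile_from_site_list(sid, "Nguni", sites, reference))
    return profiles


def fixture_population_set(
    reference: ReferenceGenome | None = None,
    tree: HaplogroupTree | None = None,
) -> PopulationSet:
    """The fixture rendered as full-length sequences, FASTA-writable.

    The shared 16201 insertion makes the raw sequences one base longer
    than the reference; because every sample carries it, the sequences
    remain mutually aligned and the insertion column behaves as a
    substitution-like character (A vs G).
    """
    reference = reference or synthetic_reference()
    profiles = generate_nguni_fixture(reference, tree)
    seqs = [mutate(reference, list(p)) for p in profiles]
    return PopulationSet(
        populations={"Nguni": seqs},
        ids={"Nguni": [p.sample_id for p in profiles]},
    )


# ---------------------------------------------------------------------------
# Serial-founder simulator
# ---------------------------------------------------------------------------

@dataclass
class FounderChainParams:
    """Parameters of the serial founder-effect simulation.

    Defaults model three populations along the historical south-bound
    chain — a North African source, an East African intermediate and the
    southern herd — with final sample sizes echoing the comparative
    datasets (26, 170, 35). Each new population is founded by
    ``chain_sizes[i]`` individuals drawn without replacement from the
    previous one, held at that size for ``bottleneck_generations``
    (the founder bottleneck), then expanded to its effective size and
    evolved for ``generations_between_steps`` under haploid
    Wright-Fisher drift with transition-biased mutation. The chain head
    is seeded at the stated subhaplogroup frequencies, each founder
    additionally carrying Poisson-distributed private mutations so the
    source population harbours realistic standing variation.
    """

    seed: int
    n_populations: int = 3
    population_names: tuple[str, ...] = ("Egypt", "Ethiopia", "Nguni")
    chain_sizes: tuple[int, ...] = (10, 10)
    final_sample_sizes: tuple[int, ...] = (26, 170, 35)
    effective_sizes: tuple[int, ...] = (1000, 1000, 1000)
    genome_length: int = BRS_LENGTH
    mutation_rate: float = 1e-7  # per site per generation
    ts_tv_ratio: float = 20.0    # mammalian-mtDNA-like transition bias
    generations_between_steps: int = 100
    bottleneck_generations: int = 1
    founder_private_mutations: float = 10.0  # Poisson mean per head founder
    haplogroup_seed_frequencies: dict[str, float] = field(
        default_factory=lambda: {
            "T1a": 0.269,
            "T1b": 0.269,
            "T1c": 0.385,
            "T1d": 0.038,
            "T1f": 0.039,
        }
    )

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        if len(self.population_names) != self.n_populations:
            raise ValueError("population_names must match n_populations")
        if len(self.chain_sizes) != self.n_populations - 1:
            raise ValueError("chain_sizes must have n_populations - 1 entries")
        if len(self.final_sample_sizes) != self.n_populations:
            raise ValueError("final_sample_sizes must match n_populations")
        if len(self.effective_sizes) != self.n_populations:
            raise ValueError("effective_sizes must match n_populations")
        if any(c < 1 for c in self.chain_sizes + self.final_sample_sizes + self.effective_sizes):
            raise ValueError("all counts must be >= 1")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")
        if self.ts_tv_ratio <= 0:
            raise ValueError("ts_tv_ratio must be > 0")
        for n_final, n_eff in zip(self.final_sample_sizes, self.effective_sizes):
            if n_final > n_eff:
                raise ValueError("final sample size exceeds effective population size")
        total = sum(self.haplogroup_seed_frequencies.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"haplogroup frequencies must sum to 1, got {total}")


@dataclass
class SimulationResult:
    """A simulated founder chain with per-sample haplogroup truth."""

    population_set: PopulationSet
    profiles: list[VariantProfile]
    haplogroup_truth: dict[str, tuple[str, ...]]
    reference: ReferenceGenome
    tree: HaplogroupTree
    params: FounderChainParams


def draw_mutated_base(current: str, rng: np.random.Generator, ts_tv_ratio: float) -> str:
    """Draw a new base: transition with odds ``ts_tv_ratio`` to 1, else
    one of the two transversion partners uniformly."""
    if rng.random() < ts_tv_ratio / (ts_tv_ratio + 1.0):
        return TRANSITION_PARTNER[current]
    partners = "CT" if current in PURINES else "AG"
    return partners[rng.integers(2)]


def _apply_mutation(
    individual: tuple[str, dict[int, str]],
    position: int,
    ref_base: str,
    rng: np.random.Generator,
    kappa: float,
) -> tuple[str, dict[int, str]]:
    hg, variants = individual
    variants = dict(variants)  # copy-on-write: parents may be shared
    current = variants.get(position, ref_base)
    new = draw_mutated_base(current, rng, kappa)
    if new == ref_base:
        variants.pop(position, None)  # back-mutation to the reference state
    else:
        variants[position] = new
    return (hg, variants)


def _evolve(
    pop: list[tuple[str, dict[int, str]]],
    size: int,
    generations: int,
    reference: ReferenceGenome,
    mu: float,
    kappa: float,
    rng: np.random.Generator,
) -> list[tuple[str, dict[int, str]]]:
    """Haploid Wright-Fisher: multinomial resampling + Poisson mutation."""
    L = len(reference)
    for _ in range(generations):
        idx = rng.integers(len(pop), size=size)
        pop = [pop[i] for i in idx]
        n_mut = rng.poisson(size * L * mu)
        for _ in range(n_mut):
            i = int(rng.integers(size))
            pos = int(rng.integers(1, L + 1))
            pop[i] = _apply_mutation(pop[i], pos, reference.base(pos), rng, kappa)
    return pop


def simulate_serial_founders(params: FounderChainParams) -> SimulationResult:
    """Run the founder-chain simulation; fully reproducible from the seed."""
    rng = np.random.default_rng(params.seed)
    ref = synthetic_reference(params.genome_length)
    tree = scaled_haplogroup_tree(params.genome_length)

    # concrete allele set for each seed haplogroup's root-to-node motif path
    def motif_variants(name: str) -> dict[int, str]:
        out: dict[int, str] = {}
        for _, m in tree.path_motifs(name):
            base = ref.base(m.position)
            if m.change == "Ts":
                out[m.position] = TRANSITION_PARTNER[base]
            else:
                _, _, alt = m.change.partition(">")
                out[m.position] = alt
        return out

    names = sorted(params.haplogroup_seed_frequencies)
    probs = np.array([params.haplogroup_seed_frequencies[n] for n in names])
    probs = probs / probs.sum()
    hap_variants = {n: motif_variants(n) for n in names}

    head_size = params.effective_sizes[0]
    pop: list[tuple[str, dict[int, str]]] = []
    for _ in range(head_size):
        hg = names[int(rng.choice(len(names), p=probs))]
        individual = (hg, dict(hap_variants[hg]))
        for _ in range(int(rng.poisson(params.founder_private_mutations))):
            pos = int(rng.integers(1, len(ref) + 1))
            individual = _apply_mutation(
                individual, pos, ref.base(pos), rng, params.ts_tv_ratio
            )
        pop.append(individual)

    populations: dict[str, list[str]] = {}
    ids: dict[str, list[str]] = {}
    truth: dict[str, tuple[str, ...]] = {}
    profiles: list[VariantProfile] = []
    for i, name in enumerate(params.population_names):
        if i > 0:
            n_founders = params.chain_sizes[i - 1]
            if n_founders > len(pop):
                raise ValueError(
                    f"founder count {n_founders} exceeds source population {len(pop)}"
                )
            founder_idx = sorted(rng.choice(len(pop), size=n_founders, replace=False))
            pop = [pop[j] for j in founder_idx]
            pop = _evolve(
                pop, n_founders, params.bottleneck_generations, ref,
                params.mutation_rate, params.ts_tv_ratio, rng,
            )
        pop = _evolve(
            pop, params.effective_sizes[i], params.generations_between_steps, ref,
            params.mutation_rate, params.ts_tv_ratio, rng,
        )
        n_final = params.final_sample_sizes[i]
        sample_idx = sorted(rng.choice(len(pop), size=n_final, replace=False))
        seqs, sids, hgs = [], [], []
        for k, j in enumerate(sample_idx, 1):
            hg, variants = pop[j]
            sid = f"{name}_{k:03d}"
            seq = list(ref.sequence)
            for pos, base in variants.items():
                seq[pos - 1] = base
            seqs.append("".join(seq))
            sids.append(sid)
            hgs.append(hg)
            profile = VariantProfile(sid, name)
            for pos in sorted(variants):
                profile.add(Variant.substitution(pos, ref.base(pos), variants[pos]))
            profiles.append(profile)
        populations[name] = seqs
        ids[name] = sids
        truth[name] = tuple(hgs)

    pop_set = PopulationSet(populations=populations, ids=ids)
    return SimulationResult(
        population_set=pop_set,
        profiles=profiles,
        haplogroup_truth=truth,
        reference=ref,
        tree=tree,
        params=params,
    )
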