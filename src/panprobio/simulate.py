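"""Seeded synthetic-data generators with planted ground truth.

Every generator is a pure function of its parameters and seed and returns
its outputs together with a :class:`SimTruth` record of the planted truth,
so downstream analyses can be validated against what was actually planted
rather than re-derived from the outputs.

Generators:

* :func:`sim_pangenome` — gene repertoires with a shared core and a
  probabilistically sampled accessory pool, plus protein sequences whose
  between-family identity stays below the clustering threshold while
  within-family copies stay above it.
* :func:`sim_divergence_pair` — a nucleotide sequence and a copy with
  substitutions planted at a controlled per-site rate, recording the true
  alignment's difference count.
* :func:`sim_modules` / :func:`sim_ko_pair` — KO-disjoint module definitions
  and a genome pair constructed to realise a target complementarity
  improvement ratio exactly.
* :func:`sim_abundance` — compositional relative-abundance tables with
  planted case/control effects and a correlated species block.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .complementarity import KOProfile, ModuleDefinition
from .microbiome import AbundanceTable

__all__ = [
    "SimTruth",
    "sim_pangenome",
    "sim_divergence_pair",
    "sim_modules",
    "sim_ko_pair",
    "sim_abundance",
]

_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1").astype("U1")
_NT = np.array(list("ACGT"))


@dataclass
class SimTruth:
    """Planted parameters and realized ground truth of one generator run."""

    generator: str
    seed: int
    params: dict
    truth: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        def _default(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"cannot serialise {type(o)}")

        text = json.dumps(asdict(self), indent=2, sort_keys=True, default=_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float,
                    max_fraction: float) -> str:
    """Substitute at per-site ``rate`` but never more than ``max_fraction``
    of the sites, keeping within-family identity above the clustering
    threshold by construction."""
    n = len(seq)
    k = min(int(rng.binomial(n, rate)), int(max_fraction * n))
    if k == 0:
        return seq
    pos = rng.choice(n, size=k, replace=False)
    chars = list(seq)
    for p in pos:
        choices = [a for a in _AA if a != chars[p]]
        chars[p] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _kmer_set(seq: str, k: int = 6) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def sim_pangenome(n_genomes: int = 10, core_size: int = 100,
                  accessory_pool: int = 200, accessory_rate: float = 0.3,
                  seed: int = 0, protein_length_range=(80, 160),
                  within_family_mut_rate: float = 0.005):
    """Simulate per-genome gene sets and protein sequences with a planted
    core/accessory structure.

    Every genome carries all ``core_size`` core families; each of the
    ``accessory_pool`` accessory families is carried independently with
    probability ``accessory_rate``. Family representative sequences are
    random proteins screened to share essentially no 6-mers (so between-
    family identity sits far below the 95% clustering threshold), and each
    genome's copy is the representative with <= 1% of sites substituted.

    Returns ``(proteins, truth)`` where ``proteins`` maps genome -> gene ->
    sequence and ``truth`` records the planted family membership and the
    closed-form pan-genome index of the planted sets.
    """
    if n_genomes <= 0 or core_size <= 0 or accessory_pool < 0:
        raise ValueError("sizes must be positive (accessory_pool may be 0)")
    if not 0.0 <= accessory_rate <= 1.0:
        raise ValueError("accessory_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_families = core_size + accessory_pool
    family_ids = [f"fam{idx:05d}" for idx in range(n_families)]

    reps: dict[str, str] = {}
    seen_kmers: set[str] = set()
    for fid in family_ids:
        for _attempt in range(100):
            length = int(rng.integers(*protein_length_range))
            cand = _random_protein(rng, length)
            km = _kmer_set(cand)
            if len(km & seen_kmers) <= 2:  # near-zero shared 6-mers
                reps[fid] = cand
                seen_kmers |= km
                break
        else:
            raise RuntimeError("could not sample a sufficiently distinct family")

    genomes = [f"g{idx:03d}" for idx in range(n_genomes)]
    carried: dict[str, list[str]] = {}
    for g in genomes:
        fams = list(family_ids[:core_size])
        draws = rng.random(accessory_pool)
        fams += [family_ids[core_size + j] for j in range(accessory_pool)
                 if draws[j] < accessory_rate]
        carried[g] = fams

    proteins = {
        g: {
            f"{fid}": _mutate_protein(rng, reps[fid], within_family_mut_rate, 0.01)
            for fid in carried[g]
        }
        for g in genomes
    }

    family_sets = {g: set(f) for g, f in ((g, carried[g]) for g in genomes)}
    pan = set().union(*family_sets.values())
    mean_per_genome = float(np.mean([len(s) for s in family_sets.values()]))
    truth = SimTruth(
        generator="sim_pangenome",
        seed=seed,
        params={"n_genomes": n_genomes, "core_size": core_size,
                "accessory_pool": accessory_pool,
                "accessory_rate": accessory_rate,
                "within_family_mut_rate": within_family_mut_rate},
        truth={
            "family_sets": {g: sorted(s) for g, s in family_sets.items()},
            "pan_family_count": len(pan),
            "mean_families_per_genome": mean_per_genome,
            "planted_pi": len(pan) / mean_per_genome,
        },
    )
    return proteins, truth


def sim_divergence_pair(length: int = 100_000, d: float = 0.05, seed: int = 0):
    """A random nucleotide sequence and a copy with substitutions at
    per-site rate ``d`` (no indels), with the realized difference count.

    Returns ``(seq_a, seq_b, truth)``; ``truth.truth['true_identity_pct']``
    is 100 * (1 - realized substitution fraction) on the known site-to-site
    alignment.
    """
    if not 0.0 <= d <= 0.3:
        raise ValueError("d must lie in [0, 0.3]")
    rng = np.random.default_rng(seed)
    a = rng.choice(_NT, size=length)
    b = a.copy()
    mutate = rng.random(length) < d
    n_mut = int(mutate.sum())
    if n_mut:
        # substitute with a uniformly random *different* base
        shift = rng.integers(1, 4, size=n_mut)
        idx_map = {"A": 0, "C": 1, "G": 2, "T": 3}
        current = np.array([idx_map[x] for x in b[mutate]])
        b[mutate] = _NT[(current + shift) % 4]
    truth = SimTruth(
        generator="sim_divergence_pair", seed=seed,
        params={"length": length, "d": d},
        truth={"n_substitutions": n_mut,
               "true_identity_pct": 100.0 * (1 - n_mut / length)},
    )
    return "".join(a), "".join(b), truth


def sim_modules(n_modules: int = 10, kos_per_module: int = 6, seed: int = 0
                ) -> list[ModuleDefinition]:
    """KO-disjoint module definitions with even required-KO counts, suitable
    for exact complementarity planting."""
    if kos_per_module % 2:
        raise ValueError("kos_per_module must be even for exact half-splits")
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, 10_000))
    modules = []
    ko = start
    for m in range(n_modules):
        kos = frozenset(f"K{ko + j:05d}" for j in range(kos_per_module))
        ko += kos_per_module
        modules.append(ModuleDefinition(f"M{m:05d}", kos))
    return modules


def sim_ko_pair(modules: list[ModuleDefinition], target_ratio: float,
                seed: int = 0):
    """Construct two KO profiles whose complementarity improvement ratio
    (max baseline) equals a planted value.

    With ``b`` modules fully present in both genomes and ``c`` modules split
    into disjoint halves, each genome totals b + c/2 and the merged set
    totals b + c, so the ratio is c / (2b + c). The generator chooses the
    (b, c) pair achievable within the module list that is closest to
    ``target_ratio`` (exact when the target is attainable) and records the
    realized ratio in the truth. Modules must be KO-disjoint with even
    required-KO counts (see :func:`sim_modules`).
    """
    if target_ratio < 0:
        raise ValueError("target_ratio must be >= 0")
    all_kos = [m.required_kos for m in modules]
    for i, ka in enumerate(all_kos):
        if len(ka) % 2:
            raise ValueError("modules must have even required-KO counts")
        for kb in all_kos[i + 1:]:
            if ka & kb:
                raise ValueError("modules must be KO-disjoint")

    m = len(modules)
    best = None  # (err, b+c, b, c)
    for b in range(m + 1):
        for c in range(m - b + 1):
            if b + c == 0:
                continue
            if c > 0 and b == 0 and target_ratio == 0:
                continue
            denom = 2 * b + c
            ratio = c / denom if denom else 0.0
            cand = (abs(ratio - target_ratio), b + c, b, c)
            if best is None or cand < best:
                best = cand
    if best is None:
        raise ValueError("no modules available")
    _, _, b, c = best
    realized = c / (2 * b + c)

    rng = np.random.default_rng(seed)
    order = list(rng.permutation(m))
    full = [modules[i] for i in order[:b]]
    split = [modules[i] for i in order[b : b + c]]
    kos_a: set[str] = set()
    kos_b: set[str] = set()
    for mod in full:
        kos_a |= mod.required_kos
        kos_b |= mod.required_kos
    for mod in split:
        kos = sorted(mod.required_kos)
        half = len(kos) // 2
        kos_a |= set(kos[:half])
        kos_b |= set(kos[half:])
    prof_a = KOProfile("sim_a", "species_A", kos_a)
    prof_b = KOProfile("sim_b", "species_B", kos_b)
    truth = SimTruth(
        generator="sim_ko_pair", seed=seed,
        params={"target_ratio": target_ratio, "n_modules": m},
        truth={"n_full_modules": b, "n_split_modules": c,
               "realized_ratio": realized,
               "full_modules": sorted(mod.module_id for mod in full),
               "split_modules": sorted(mod.module_id for mod in split)},
    )
    return prof_a, prof_b, truth


@dataclass(frozen=True)
class BlockSpec:
    """Planted co-abundance block: ``n_species`` case-enriched species share
    a latent log-scale factor tuned to a linear-scale Pearson target."""

    n_species: int = 5
    target_cc: float = 0.8


def sim_abundance(n_case: int = 100, n_control: int = 100,
                  n_species: int = 150, n_enriched: int = 20,
                  effect_fold: float = 4.0,
                  block_spec: BlockSpec | None = BlockSpec(),
                  seed: int = 0, log_sigma: float = 1.5):
    """Simulate a compositional relative-abundance table with planted
    case/control effects and a correlated species block.

    Log-abundances are normal with species-specific means and common scale
    ``log_sigma`` (natural log; the default spans several orders of
    magnitude, as real species profiles do). The first half of the planted
    enriched species is raised ``effect_fold``-fold in cases, the second
    half in controls. Block species (case-enriched ones) additionally share
    a latent factor whose loading is chosen by inverting the lognormal
    correlation attenuation formula at ``target_cc``. Rows are renormalized
    to sum to 100, making all effects compositional.

    Returns ``(AbundanceTable, truth)`` with planted directions and expected
    co-abundance edges in the truth.
    """
    if n_enriched > n_species:
        raise ValueError("n_enriched cannot exceed n_species")
    if block_spec is not None and block_spec.n_species > max(1, n_enriched // 2):
        raise ValueError("block must fit inside the case-enriched species")
    rng = np.random.default_rng(seed)
    species = [f"s__species_{idx:04d}" for idx in range(n_species)]
    samples = [f"case_{idx:04d}" for idx in range(n_case)] + \
              [f"ctrl_{idx:04d}" for idx in range(n_control)]
    groups = pd.Series(["case"] * n_case + ["control"] * n_control, index=samples)

    enriched_idx = rng.choice(n_species, size=n_enriched, replace=False)
    case_up = sorted(int(i) for i in enriched_idx[: n_enriched // 2])
    ctrl_up = sorted(int(i) for i in enriched_idx[n_enriched // 2:])
    block_idx = case_up[: block_spec.n_species] if block_spec else []

    mu = rng.normal(0.0, 2.0, size=n_species)  # species-specific log means
    # planted differential species are sub-dominant taxa (as real disease
    # markers typically are), so their fold-changes barely move per-sample
    # totals and the compositional closure does not flip null species
    mu[enriched_idx] = rng.normal(-2.0, 1.0, size=n_enriched)
    n = n_case + n_control
    eps = rng.normal(0.0, 1.0, size=(n, n_species))
    log_x = mu[None, :] + log_sigma * eps

    if block_spec and block_idx:
        # lognormal attenuation: corr_linear = (exp(rho s^2)-1)/(exp(s^2)-1)
        s2 = log_sigma ** 2
        rho = np.log(block_spec.target_cc * (np.exp(s2) - 1) + 1) / s2
        rho = min(max(rho, 0.0), 0.999)
        z = rng.normal(0.0, 1.0, size=n)
        for j in block_idx:
            log_x[:, j] = (mu[j] + log_sigma *
                           (np.sqrt(rho) * z + np.sqrt(1 - rho) * eps[:, j]))

    log_fold = np.log(effect_fold)
    is_case = (groups == "case").to_numpy()
    for j in case_up:
        log_x[is_case, j] += log_fold
    for j in ctrl_up:
        log_x[~is_case, j] += log_fold

    x = np.exp(log_x)
    x = 100.0 * x / x.sum(axis=1, keepdims=True)
    data = pd.DataFrame(x, index=samples, columns=species)
    table = AbundanceTable(data, groups, scale=100.0)

    block_species = [species[j] for j in block_idx]
    expected_edges = sorted(
        tuple(sorted((a, b)))
        for i, a in enumerate(block_species) for b in block_species[i + 1:]
    )
    truth = SimTruth(
        generator="sim_abundance", seed=seed,
        params={"n_case": n_case, "n_control": n_control,
                "n_species": n_species, "n_enriched": n_enriched,
                "effect_fold": effect_fold, "log_sigma": log_sigma,
                "block": asdict(block_spec) if block_spec else None},
        truth={
            "case_enriched": [species[j] for j in case_up],
            "control_enriched": [species[j] for j in ctrl_up],
            "block_species": block_species,
            "expected_edges": [list(e) for e in expected_edges],
        },
    )
    return table, truth
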