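"""Synthetic community, sequence, and phenotype generators with ground truth.

The count model is Dirichlet-multinomial around a log-normal base profile.
Treatment effects multiply planted taxa in drought samples of affected
ecotypes; correlated taxon modules are induced by one latent Gaussian factor
per module applied before renormalization (Gaussian-copula style). All draws
are bit-stable given the spec seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import RANKS, CountTable, StudyDesign, TaxonomyTable

_PROFILE_KEY = 0x00BA5E
_TAXONOMY_KEY = 0x007A10
_COMMUNITY_KEY = 0x00C0DE
_SEQUENCE_KEY = 0x005EC5
_PHENOTYPE_KEY = 0x00FE07

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass(frozen=True)
class PlantedEffect:
    """A treatment effect: ``taxa`` change ``fold``-fold under drought in ``ecotypes``."""

    taxa: tuple
    ecotypes: tuple
    fold: float
    direction: str = "enriched"

    def __post_init__(self):
        if self.fold <= 0:
            raise ValueError("fold must be > 0")
        if self.direction not in ("enriched", "depleted"):
            raise ValueError(f"unknown direction: {self.direction!r}")


@dataclass(frozen=True)
class CorrelationModule:
    """Taxa sharing a latent factor with loading ``loading`` in [0, 1]."""

    taxa: tuple
    loading: float

    def __post_init__(self):
        if not 0.0 <= self.loading <= 1.0:
            raise ValueError("module loading must lie in [0, 1]")


@dataclass
class SyntheticSpec:
    n_ecotypes: int = 10
    n_reps: int = 4
    n_taxa: int = 300
    depth_range: tuple = (5_000, 20_000)
    base_sigma: float = 1.5
    theta: float = 5_000.0  # Dirichlet concentration; larger = less overdispersion
    planted_effects: tuple = ()
    group_differential: float = 1.0  # extra fold multiplier in tolerant ecotypes
    network_modules: tuple = ()
    n_bulk_reps: int = 0
    module_scale: float = 1.0  # latent factor is exp(loading * scale * z)
    tolerance_factors: tuple = (0.75, 0.40)  # drought/control weight ratio (tolerant, sensitive)
    protected_ecotypes: tuple = ()
    protection_factor: float = 1.0  # extra live-soil drought survival in protected ecotypes
    pheno_mean_mg: float = 200.0
    pheno_cv: float = 0.05
    seed: int = 0

    def __post_init__(self):
        self.planted_effects = tuple(
            e if isinstance(e, PlantedEffect) else PlantedEffect(**e) for e in self.planted_effects
        )
        self.network_modules = tuple(
            m if isinstance(m, CorrelationModule) else CorrelationModule(**m)
            for m in self.network_modules
        )
        for group, items in (
            ("planted_effects", [e.taxa for e in self.planted_effects]),
            ("network_modules", [m.taxa for m in self.network_modules]),
        ):
            seen: set = set()
            for taxa in items:
                for t in taxa:
                    if not 0 <= int(t) < self.n_taxa:
                        raise ValueError(f"{group} taxon index {t} out of range")
                    if t in seen:
                        raise ValueError(f"{group} taxon sets must be disjoint (index {t})")
                    seen.add(t)

    def ecotype_names(self):
        return [f"E{i + 1:02d}" for i in range(self.n_ecotypes)]

    def tolerance_class_of(self, ecotype: str) -> str:
        if ecotype == "bulk":
            return "bulk"
        names = self.ecotype_names()
        return "tolerant" if names.index(ecotype) < self.n_ecotypes // 2 else "sensitive"


@dataclass
class PlantedTruth:
    """Ground-truth labels accompanying one generated dataset."""

    core_status: dict  # taxon_id -> {enriched, depleted, null}
    affected_ecotypes: dict  # taxon_id -> list of ecotype names
    true_fold: dict  # taxon_id -> fold under drought in affected ecotypes
    module_of: dict  # taxon_id -> module index (planted modules only)
    tolerance_class: dict  # ecotype -> {tolerant, sensitive}
    phenotype_factor: dict = field(default_factory=dict)  # ecotype -> drought weight ratio

    def core_taxa(self, direction="enriched"):
        return sorted(t for t, s in self.core_status.items() if s == direction)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(**doc)


def _rng(spec_seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(spec_seed), key)))


def base_profile(spec: SyntheticSpec) -> np.ndarray:
    """Mean relative-abundance profile; depends only on seed, n_taxa, base_sigma."""
    rng = _rng(spec.seed, _PROFILE_KEY)
    raw = rng.lognormal(mean=0.0, sigma=spec.base_sigma, size=spec.n_taxa)
    return raw / raw.sum()


def eligible_planted_taxa(spec: SyntheticSpec, min_base_abundance=0.002) -> list:
    """Indices of taxa abundant enough for planted effects to be detectable."""
    profile = base_profile(spec)
    return [int(i) for i in np.argsort(profile)[::-1] if profile[i] >= min_base_abundance]

def _taxon_ids(n):
    return [f"ASV{i + 1}" for i in range(n)]


def generate_taxonomy(spec: SyntheticSpec) -> TaxonomyTable:
    """Random but deterministic 7-rank lineages; ~10% lack a genus annotation."""
    rng = _rng(spec.seed, _TAXONOMY_KEY)
    phyla = [f"Phylum{i}" for i in range(1, 7)]
    n_families = max(2, spec.n_taxa // 10)
    n_genera = max(2, spec.n_taxa // 3)
    rows = []
    for i in range(spec.n_taxa):
        fam = int(rng.integers(n_families))
        genus = f"Genus{int(rng.integers(n_genera)) + 1:03d}"
        if rng.random() < 0.1:
            genus = ""  # unannotated; rendered with the sentinel suffix
        rows.append(
            {
                "kingdom": "Bacteria",
                "phylum": phyla[fam % len(phyla)],
                "class": f"Class{fam % 12 + 1}",
                "order": f"Order{fam % 25 + 1}",
                "family": f"Family{fam + 1:03d}",
                "genus": genus,
                "species": "",
            }
        )
    frame = pd.DataFrame(rows, index=_taxon_ids(spec.n_taxa))
    return TaxonomyTable(frame)


def generate_community(spec: SyntheticSpec):
    """Draw one full dataset: counts, design, taxonomy, and planted truth."""
    rng = _rng(spec.seed, _COMMUNITY_KEY)
    profile = base_profile(spec)
    taxonomy = generate_taxonomy(spec)
    taxon_ids = _taxon_ids(spec.n_taxa)

    ecotypes = spec.ecotype_names()
    design_rows = []
    sample_ids = []
    contexts = []
    for eco in ecotypes:
        for treatment in ("control", "drought"):
            for rep in range(1, spec.n_reps + 1):
                sid = f"{eco}.{treatment}.r{rep}"
                sample_ids.append(sid)
                contexts.append((eco, treatment))
                design_rows.append(
                    {
                        "ecotype": eco,
                        "treatment": treatment,
                        "tolerance_class": spec.tolerance_class_of(eco),
                        "replicate": rep,
                    }
                )
    for treatment in ("control", "drought"):
        for rep in range(1, spec.n_bulk_reps + 1):
            sid = f"bulk.{treatment}.r{rep}"
            sample_ids.append(sid)
            contexts.append(("bulk", treatment))
            design_rows.append(
                {
                    "ecotype": "bulk",
                    "treatment": treatment,
                    "tolerance_class": "bulk",
                    "replicate": rep,
                }
            )

    lo, hi = spec.depth_range
    counts = np.zeros((len(sample_ids), spec.n_taxa), dtype=np.int64)
    for row, (eco, treatment) in enumerate(contexts):
        p = profile.copy()
        if eco != "bulk" and treatment == "drought":
            tolerant = spec.tolerance_class_of(eco) == "tolerant"
            for eff in spec.planted_effects:
                if eco in eff.ecotypes:
                    f = eff.fold * (spec.group_differential if tolerant else 1.0)
                    idx = np.asarray(eff.taxa, dtype=int)
                    p[idx] = p[idx] * f if eff.direction == "enriched" else p[idx] / f
        for mod in spec.network_modules:
            z = rng.standard_normal()
            idx = np.asarray(mod.taxa, dtype=int)
            p[idx] = p[idx] * np.exp(mod.loading * spec.module_scale * z)
        p /= p.sum()
        depth = int(rng.integers(lo, hi + 1))
        composition = rng.dirichlet(p * spec.theta)
        counts[row] = rng.multinomial(depth, composition)

    # a zero-total sample would violate the CountTable invariant; with any
    # realistic depth this cannot happen, but guard the degenerate spec
    empty = counts.sum(axis=1) == 0
    if empty.any():
        counts[empty, 0] = 1

    table = CountTable(sample_ids, taxon_ids, counts)
    design = StudyDesign(pd.DataFrame(design_rows, index=sample_ids))

    core_status = {t: "null" for t in taxon_ids}
    affected = {}
    folds = {}
    for eff in spec.planted_effects:
        for t in eff.taxa:
            tid = taxon_ids[int(t)]
            core_status[tid] = eff.direction
            affected[tid] = list(eff.ecotypes)
            folds[tid] = eff.fold
    module_of = {}
    for k, mod in enumerate(spec.network_modules):
        for t in mod.taxa:
            module_of[taxon_ids[int(t)]] = k
    tolerance = {e: spec.tolerance_class_of(e) for e in ecotypes}
    factor = {
        e: (spec.tolerance_factors[0] if tolerance[e] == "tolerant" else spec.tolerance_factors[1])
        for e in ecotypes
    }
    truth = PlantedTruth(
        core_status=core_status,
        affected_ecotypes=affected,
        true_fold=folds,
        module_of=module_of,
        tolerance_class=tolerance,
        phenotype_factor=factor,
    )
    return table, design, truth, taxonomy


# ---------------------------------------------------------------------------
# Sequences


def _random_sequences(rng, n, length):
    return ["".join(_BASES[rng.integers(0, 4, size=length)]) for _ in range(n)]


def _mutate(rng, seq: str, rate: float) -> str:
    """Substitute each position independently at ``rate``; no indels."""
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def generate_sequences(n_asvs, n_isolates, divergence, seed, length=420):
    """V3-V4-like ASV sequences plus isolates derived from them.

    Each isolate is a copy of a cyclically chosen source ASV with i.i.d.
    substitutions at ``divergence``. Returns (asv records, isolate records,
    pairing dict isolate_id -> source asv_id) with records as (id, sequence).
    """
    if not 0.0 <= divergence <= 0.2:
        raise ValueError("divergence must lie in [0, 0.2]")
    rng = _rng(seed, _SEQUENCE_KEY)
    asv_ids = _taxon_ids(n_asvs)
    asv_seqs = _random_sequences(rng, n_asvs, length)
    asvs = list(zip(asv_ids, asv_seqs))
    isolates = []
    pairing = {}
    for j in range(n_isolates):
        src = j % n_asvs
        iso_id = f"ISO{j + 1}"
        isolates.append((iso_id, _mutate(rng, asv_seqs[src], divergence)))
        pairing[iso_id] = asv_ids[src]
    return asvs, isolates, pairing


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Phenotypes


def generate_phenotypes(truth: PlantedTruth, spec: SyntheticSpec, n_plants=8) -> pd.DataFrame:
    """Shoot fresh weights and wilting scores for live and sterilized soil.

    Control weights are Normal around the ecotype mean; drought weights are
    the control mean times the tolerance factor (times the protection factor
    in live soil of protected ecotypes) with multiplicative noise. Wilting
    scores map the realized weight ratio monotonically onto the 1-5 scale.
    """
    rng = _rng(spec.seed, _PHENOTYPE_KEY)
    rows = []
    for eco, factor in truth.phenotype_factor.items():
        for soil in ("live", "sterilized"):
            eff = factor
            if soil == "live" and eco in spec.protected_ecotypes:
                eff = min(1.0, factor * spec.protection_factor)
            for treatment in ("control", "drought"):
                mean = spec.pheno_mean_mg if treatment == "control" else spec.pheno_mean_mg * eff
                for k in range(n_plants):
                    noise = rng.normal(0.0, spec.pheno_cv) if spec.pheno_cv > 0 else 0.0
                    weight = max(mean * (1.0 + noise), 1e-6)
                    ratio = weight / spec.pheno_mean_mg
                    if treatment == "control":
                        score = 5
                    else:
                        score = int(np.clip(round(1 + 4 * ratio), 1, 5))
                    rows.append(
                        {
                            "plant_id": f"{eco}.{soil}.{treatment}.p{k + 1}",
                            "ecotype": eco,
                            "treatment": treatment,
                            "soil_state": soil,
                            "fresh_weight_mg": weight,
                            "wilting_score": score,
                        }
                    )
    return pd.DataFrame(rows).set_index("plant_id")
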