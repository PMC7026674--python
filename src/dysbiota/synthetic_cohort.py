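"""Synthetic hospital-cohort generator.

Emulates the statistical structure of a gastroenterology ward study:
121 hospitalized patients (five diagnosis groups) and 162 healthy
controls, each with a bacterial (16S) and fungal (ITS2) stool community.
Hospitalized subjects belong to one of three latent dysbiosis states:

* ``C1`` -- healthy-like community (all controls are C1 by construction);
* ``C2`` -- bloom of Enterobacteriaceae (*Escherichia/Shigella* and
  relatives), mild loss of strict anaerobes;
* ``C3`` -- bloom of *Enterococcus* and *Streptococcus* with strong
  loss of *Faecalibacterium*, *Roseburia* and *Blautia*.

Counts are Dirichlet-multinomial: cluster and hospitalization effects act
additively on log relative abundance, the perturbed composition is
renormalized, a per-sample composition is drawn from a Dirichlet with
concentration ``overdispersion x composition``, and reads are drawn
multinomially at a uniformly drawn depth.  C-reactive protein is linear
in the realized *Enterococcus* relative abundance, so the generator owns
a configurable CRP-*Enterococcus* correlation target; leukocyte and
neutrophil counts receive an additive shift in C3.

Randomness is one stream per cohort split by subject index
(``SeedSequence(seed, spawn_key=(i,))``), so appending subjects never
perturbs earlier subjects' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CLUSTER_NAMES, DIAGNOSIS_LEAVES, OtuTable, SampleMetadata

__all__ = ["CohortConfig", "generate_cohort", "sample_inflammation"]

# ---------------------------------------------------------------- taxa

_BACT_LINEAGES: dict[str, tuple[str, ...]] = {
    "Faecalibacterium": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Faecalibacterium"),
    "Roseburia": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Roseburia"),
    "Blautia": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Blautia"),
    "Escherichia/Shigella": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacteriales", "Enterobacteriaceae", "Escherichia/Shigella"),
    "Enterobacteriaceae_other": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacteriales", "Enterobacteriaceae", "unclassified"),
    "Enterococcus": ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Enterococcaceae", "Enterococcus"),
    "Streptococcus": ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
}

_BACT_FILLER = [
    ("Bacteroides", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae"),
    ("Prevotella", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae"),
    ("Alistipes", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Rikenellaceae"),
    ("Parabacteroides", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae"),
    ("Barnesiella", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae"),
    ("Ruminococcus", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae"),
    ("Subdoligranulum", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae"),
    ("Oscillibacter", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae"),
    ("Anaerostipes", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    ("Coprococcus", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    ("Dorea", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    ("Fusicatenibacter", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    ("Lachnoclostridium", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    ("Eubacterium", "Firmicutes", "Clostridia", "Clostridiales", "Eubacteriaceae"),
    ("Clostridium_XlVa", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    ("Dialister", "Firmicutes", "Negativicutes", "Selenomonadales", "Veillonellaceae"),
    ("Veillonella", "Firmicutes", "Negativicutes", "Selenomonadales", "Veillonellaceae"),
    ("Phascolarctobacterium", "Firmicutes", "Negativicutes", "Selenomonadales", "Acidaminococcaceae"),
    ("Lactobacillus", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae"),
    ("Bifidobacterium", "Actinobacteria", "Actinobacteria", "Bifidobacteriales", "Bifidobacteriaceae"),
    ("Collinsella", "Actinobacteria", "Coriobacteriia", "Coriobacteriales", "Coriobacteriaceae"),
    ("Akkermansia", "Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales", "Verrucomicrobiaceae"),
    ("Sutterella", "Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Sutterellaceae"),
    ("Parasutterella", "Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Sutterellaceae"),
    ("Desulfovibrio", "Proteobacteria", "Deltaproteobacteria", "Desulfovibrionales", "Desulfovibrionaceae"),
    ("Haemophilus", "Proteobacteria", "Gammaproteobacteria", "Pasteurellales", "Pasteurellaceae"),
    ("Fusobacterium", "Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae"),
    ("Odoribacter", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Odoribacteraceae"),
    ("Butyricimonas", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Odoribacteraceae"),
    ("Roseburia_other", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    ("Clostridium_IV", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae"),
    ("Gemmiger", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae"),
    ("Megasphaera", "Firmicutes", "Negativicutes", "Selenomonadales", "Veillonellaceae"),
]
for name, phylum, cls, order, fam in _BACT_FILLER:
    _BACT_LINEAGES[name] = ("Bacteria", phylum, cls, order, fam, name)

_FUNGI_LINEAGES: dict[str, tuple[str, ...]] = {
    "S_cerevisiae": ("Fungi", "Ascomycota", "Saccharomycetes", "Saccharomycetales", "Saccharomycetaceae", "Saccharomyces"),
    "C_albicans": ("Fungi", "Ascomycota", "Saccharomycetes", "Saccharomycetales", "Debaryomycetaceae", "Candida"),
    "C_glabrata": ("Fungi", "Ascomycota", "Saccharomycetes", "Saccharomycetales", "Saccharomycetaceae", "Nakaseomyces"),
    "Debaryomyces": ("Fungi", "Ascomycota", "Saccharomycetes", "Saccharomycetales", "Debaryomycetaceae", "Debaryomyces"),
    "Pichia": ("Fungi", "Ascomycota", "Saccharomycetes", "Saccharomycetales", "Pichiaceae", "Pichia"),
    "Kluyveromyces": ("Fungi", "Ascomycota", "Saccharomycetes", "Saccharomycetales", "Saccharomycetaceae", "Kluyveromyces"),
    "Penicillium": ("Fungi", "Ascomycota", "Eurotiomycetes", "Eurotiales", "Aspergillaceae", "Penicillium"),
    "Aspergillus": ("Fungi", "Ascomycota", "Eurotiomycetes", "Eurotiales", "Aspergillaceae", "Aspergillus"),
    "Cladosporium": ("Fungi", "Ascomycota", "Dothideomycetes", "Capnodiales", "Cladosporiaceae", "Cladosporium"),
    "Malassezia": ("Fungi", "Basidiomycota", "Malasseziomycetes", "Malasseziales", "Malasseziaceae", "Malassezia"),
    "Galactomyces": ("Fungi", "Ascomycota", "Saccharomycetes", "Saccharomycetales", "Dipodascaceae", "Galactomyces"),
    "Mucor": ("Fungi", "Mucoromycota", "Mucoromycetes", "Mucorales", "Mucoraceae", "Mucor"),
}


def _default_base_profile_bact() -> dict[str, float]:
    named = {
        "Faecalibacterium": 0.10,
        "Roseburia": 0.06,
        "Blautia": 0.08,
        "Escherichia/Shigella": 0.010,
        "Enterobacteriaceae_other": 0.005,
        "Enterococcus": 0.002,
        "Streptococcus": 0.010,
    }
    fillers = [name for name, *_ in _BACT_FILLER]
    # geometric decay over filler taxa, scaled to the remaining mass
    w = 0.85 ** np.arange(len(fillers))
    w = w / w.sum() * (1.0 - sum(named.values()))
    profile = dict(named)
    profile.update({name: float(x) for name, x in zip(fillers, w)})
    total = sum(profile.values())
    return {k: v / total for k, v in profile.items()}


def _default_base_profile_fungi() -> dict[str, float]:
    named = {"S_cerevisiae": 0.55, "C_albicans": 0.10}
    fillers = [t for t in _FUNGI_LINEAGES if t not in named]
    w = 0.7 ** np.arange(len(fillers))
    w = w / w.sum() * (1.0 - sum(named.values()))
    profile = dict(named)
    profile.update({name: float(x) for name, x in zip(fillers, w)})
    total = sum(profile.values())
    return {k: v / total for k, v in profile.items()}


def _default_effect_matrix() -> dict[str, dict[str, float]]:
    return {
        "C1": {},
        "C2": {
            "Escherichia/Shigella": 4.5,
            "Enterobacteriaceae_other": 4.0,
            "Enterococcus": 1.2,
            "Faecalibacterium": -1.5,
            "Roseburia": -1.5,
            "Blautia": -0.5,
            "C_albicans": 2.0,
            "S_cerevisiae": -1.5,
        },
        "C3": {
            "Enterococcus": 6.5,
            "Streptococcus": 3.0,
            "Faecalibacterium": -2.5,
            "Roseburia": -2.5,
            "Blautia": -2.0,
            "C_albicans": 2.0,
            "S_cerevisiae": -1.5,
        },
    }


def _default_hospitalized_effect() -> dict[str, float]:
    # mild community disruption shared by all hospitalized subjects,
    # including the healthy-like C1 patients
    return {
        "Faecalibacterium": -0.7,
        "Roseburia": -0.7,
        "Streptococcus": 1.0,
        "Escherichia/Shigella": 0.8,
        "S_cerevisiae": -1.0,
        "C_albicans": 0.8,
    }


_HP_LEAVES = ("CD", "UC", "Infection", "Tumor", "Other")


def _default_cluster_probs() -> dict[tuple[str, bool], tuple[float, float, float]]:
    probs: dict[tuple[str, bool], tuple[float, float, float]] = {}
    for leaf in _HP_LEAVES:
        probs[(leaf, True)] = (0.32, 0.42, 0.26)
        probs[(leaf, False)] = (0.74, 0.22, 0.04)
    probs[("NHC", True)] = (1.0, 0.0, 0.0)
    probs[("NHC", False)] = (1.0, 0.0, 0.0)
    return probs


@dataclass
class CohortConfig:
    """Generator configuration; defaults emulate the study cohort
    (group sizes, ages, sex ratios and antibiotic rates of its Table of
    host factors, and the three-cluster dysbiosis structure)."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"CD": 15, "UC": 25, "Infection": 23, "Tumor": 22, "Other": 36, "NHC": 162}
    )
    cluster_probs: dict[tuple[str, bool], tuple[float, float, float]] = field(default_factory=_default_cluster_probs)
    antibiotic_prob: dict[str, float] = field(
        default_factory=lambda: {"CD": 0.533, "UC": 0.320, "Infection": 0.696, "Tumor": 0.273, "Other": 0.333, "NHC": 0.056}
    )
    age_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "CD": (41.1, 15.0), "UC": (46.2, 14.6), "Infection": (64.6, 10.9),
            "Tumor": (69.2, 10.9), "Other": (58.0, 14.1), "NHC": (45.1, 15.5),
        }
    )
    female_prob: dict[str, float] = field(
        default_factory=lambda: {"CD": 0.60, "UC": 0.48, "Infection": 0.478, "Tumor": 0.409, "Other": 0.528, "NHC": 0.642}
    )
    base_profile_bact: dict[str, float] = field(default_factory=_default_base_profile_bact)
    base_profile_fungi: dict[str, float] = field(default_factory=_default_base_profile_fungi)
    effect_matrix: dict[str, dict[str, float]] = field(default_factory=_default_effect_matrix)
    hospitalized_effect: dict[str, float] = field(default_factory=_default_hospitalized_effect)
    overdispersion: float = 50.0
    depth_range_bact: tuple[int, int] = (3000, 60000)
    depth_range_fungi: tuple[int, int] = (800, 30000)
    #: CRP (mg/L) = intercept + slope * Enterococcus relative abundance + N(0, sd)
    crp_model: tuple[float, float, float] = (25.0, 90.0, 34.0)
    #: leukocytes (1e9/L): (baseline, additive C3 shift, sd)
    leuko_model: tuple[float, float, float] = (7.0, 5.0, 2.0)
    neutro_model: tuple[float, float, float] = (4.5, 4.0, 1.5)
    age_bounds: tuple[float, float] = (18.0, 80.0)
    seed: int = 0

    def validate(self) -> None:
        for leaf, n in self.n_per_group.items():
            if leaf not in DIAGNOSIS_LEAVES:
                raise ValueError(f"unknown diagnosis leaf in n_per_group: {leaf!r}")
            if n < 0:
                raise ValueError("group sizes must be >= 0")
        for key, p in self.cluster_probs.items():
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(f"cluster_probs{key} does not sum to 1")
            if any(x < 0 for x in p):
                raise ValueError(f"cluster_probs{key} has negative entries")
        for name, profile in (("bacterial", self.base_profile_bact), ("fungal", self.base_profile_fungi)):
            vals = np.array(list(profile.values()))
            if (vals < 0).any():
                raise ValueError(f"{name} base profile has negative entries")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} base profile does not sum to 1")
        if not self.overdispersion > 0:
            raise ValueError("overdispersion must be > 0")
        for rng_ in (self.depth_range_bact, self.depth_range_fungi):
            if rng_[0] < 1 or rng_[1] < rng_[0]:
                raise ValueError("depth ranges must be positive and ordered")


def sample_inflammation(
    enterococcus_rel: float,
    true_cluster: str,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """Draw (CRP, leukocytes, neutrophils) for one hospitalized subject.

    CRP is linear in the *Enterococcus* relative abundance; leukocyte and
    neutrophil counts receive the configured additive shift in cluster C3.
    All three are truncated at zero.
    """
    if not 0.0 <= enterococcus_rel <= 1.0:
        raise ValueError("enterococcus_rel must be in [0, 1]")
    ic, slope, sd = config.crp_model
    crp = max(0.0, ic + slope * enterococcus_rel + (rng.normal(0.0, sd) if sd > 0 else 0.0))
    out = [crp]
    for base, shift, msd in (config.leuko_model, config.neutro_model):
        v = base + (shift if true_cluster == "C3" else 0.0)
        v += rng.normal(0.0, msd) if msd > 0 else 0.0
        out.append(max(0.0, v))
    return tuple(out)  # type: ignore[return-value]


def _draw_counts(
    base: np.ndarray,
    lfc: np.ndarray,
    overdispersion: float,
    depth_range: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    with np.errstate(divide="ignore"):
        logp = np.where(base > 0, np.log(np.maximum(base, 1e-300)) + lfc, -np.inf)
    logp -= logp.max()
    comp = np.exp(logp)
    comp /= comp.sum()
    alpha = np.maximum(overdispersion * comp, 1e-12)
    theta = rng.dirichlet(alpha)
    depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
    return rng.multinomial(depth, theta)


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[OtuTable, OtuTable, list[SampleMetadata]]:
    """Generate a full cohort: bacterial table, fungal table, metadata.

    Deterministic given ``config.seed``; each subject consumes an
    independent child stream keyed by its index.
    """
    config = config or CohortConfig()
    config.validate()

    bact_taxa = list(config.base_profile_bact)
    fungi_taxa = list(config.base_profile_fungi)
    base_b = np.array([config.base_profile_bact[t] for t in bact_taxa])
    base_f = np.array([config.base_profile_fungi[t] for t in fungi_taxa])

    def lfc_vector(taxa: list[str], cluster: str, hospitalized: bool) -> np.ndarray:
        eff = config.effect_matrix.get(cluster, {})
        hosp = config.hospitalized_effect if hospitalized else {}
        return np.array([eff.get(t, 0.0) + hosp.get(t, 0.0) for t in taxa])

    records: list[SampleMetadata] = []
    bact_rows: list[np.ndarray] = []
    fungi_rows: list[np.ndarray] = []
    subject_index = 0
    entero_col = bact_taxa.index("Enterococcus") if "Enterococcus" in bact_taxa else None

    for leaf in DIAGNOSIS_LEAVES:
        n = config.n_per_group.get(leaf, 0)
        for j in range(n):
            rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(subject_index,)))
            hospitalized = leaf != "NHC"
            mean, sd = config.age_mean_sd[leaf]
            age = float(np.clip(rng.normal(mean, sd), *config.age_bounds))
            gender = "F" if rng.random() < config.female_prob[leaf] else "M"
            antibiotic = bool(rng.random() < config.antibiotic_prob[leaf])
            if not hospitalized:
                cluster = "C1"
            else:
                probs = config.cluster_probs.get((leaf, antibiotic))
                if probs is None:
                    raise ValueError(f"no cluster probabilities for ({leaf}, {antibiotic})")
                cluster = CLUSTER_NAMES[int(rng.choice(3, p=np.asarray(probs) / np.sum(probs)))]

            bact = _draw_counts(base_b, lfc_vector(bact_taxa, cluster, hospitalized),
                                config.overdispersion, config.depth_range_bact, rng)
            fungi = _draw_counts(base_f, lfc_vector(fungi_taxa, cluster, hospitalized),
                                 config.overdispersion, config.depth_range_fungi, rng)

            if hospitalized:
                entero_rel = float(bact[entero_col] / bact.sum()) if entero_col is not None else 0.0
                crp, leuko, neutro = sample_inflammation(entero_rel, cluster, config, rng)
            else:
                crp = leuko = neutro = float("nan")

            sid = f"{'HP' if hospitalized else 'NHC'}{subject_index:03d}"
            records.append(
                SampleMetadata(
                    subject_id=sid, diagnosis_leaf=leaf, hospitalized=hospitalized,
                    age=age, gender=gender, antibiotic=antibiotic, true_cluster=cluster,
                    crp=crp, leukocytes=leuko, neutrophils=neutro,
                )
            )
            bact_rows.append(bact)
            fungi_rows.append(fungi)
            subject_index += 1

    ids = [r.subject_id for r in records]
    otu_ids_b = [f"BOtu{i + 1:03d}" for i in range(len(bact_taxa))]
    otu_ids_f = [f"FOtu{i + 1:03d}" for i in range(len(fungi_taxa))]
    tax_b = {oid: _BACT_LINEAGES.get(t, ("Bacteria",) + ("unclassified",) * 4 + (t,))
             for oid, t in zip(otu_ids_b, bact_taxa)}
    tax_f = {oid: _FUNGI_LINEAGES.get(t, ("Fungi",) + ("unclassified",) * 4 + (t,))
             for oid, t in zip(otu_ids_f, fungi_taxa)}

    bact_table = OtuTable(pd.DataFrame(np.array(bact_rows, dtype=np.int64), index=ids, columns=otu_ids_b), tax_b)
    fungi_table = OtuTable(pd.DataFrame(np.array(fungi_rows, dtype=np.int64), index=ids, columns=otu_ids_f), tax_f)
    return bact_table, fungi_table, records


def taxon_otu_map(config: CohortConfig | None = None) -> dict[str, str]:
    """Map generator taxon names to the OTU ids used in generated tables."""
    config = config or CohortConfig()
    out = {t: f"BOtu{i + 1:03d}" for i, t in enumerate(config.base_profile_bact)}
    out.update({t: f"FOtu{i + 1:03d}" for i, t in enumerate(config.base_profile_fungi)})
    return out
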