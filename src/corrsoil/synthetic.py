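"""Ground-truthed synthetic data for every analysis stage.

Each generator emulates one of the study's data streams and returns the
dataset together with a :class:`SimulationTruth` recording everything the
generator decided (roles, K_d, responder identities, effect sizes), so that
downstream recovery tests read planted truth rather than re-deriving it.
Regeneration from the same (scenario, seed) is deterministic.

Emulated designs
----------------
* annotation tables: one row per (genome, detected identifier) with a
  semicolon lineage, as produced by annotation pipelines for MAG sets;
* serial extractions: the equilibrium forward model — the soil pool decays
  by 1/(1 + K_d*vol_aq/vol_soil) per round, the aqueous phase is K_d times
  the soil pool — with multiplicative lognormal measurement noise;
* community tables: 7 corrinoid treatments (water control plus six
  corrinoids) x replicates x timepoints; the enrichment design uses two
  media (M9, R2), six replicates and one uninoculated control per condition
  at weeks 1, 2, 12, 14; the microcosm design uses soil, five replicates and
  days 0, 3, 10, 30, 50. Expected relative abundances are log-normal across
  taxa; designated responder taxa are multiplied by per-corrinoid fold
  changes (suppression, FC < 1, is allowed) before renormalisation; counts
  are multinomial at the requested sequencing depth (optionally
  Dirichlet-multinomial via ``overdispersion``);
* standard curves: a monotone four-parameter-logistic response with plateau
  at the configured saturation concentration (default 1 nM).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community import CORRINOIDS, RANKS, FeatureTable
from .genome_roles import (
    DEFAULT_MARKER_CONFIG,
    GenomeAnnotation,
    MarkerConfig,
    ROLES,
)
from .partition import ExtractionGeometry, ExtractionRound, ExtractionSeries

__all__ = [
    "SimulationTruth",
    "gen_annotations",
    "gen_study_annotation_standin",
    "gen_extraction_series",
    "gen_community",
    "gen_standard_curve",
]


@dataclass(frozen=True)
class SimulationTruth:
    """Machine-readable record of what a generator planted."""

    scenario: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(f"not serializable: {type(o)}")

        return json.dumps(dataclasses.asdict(self), default=default, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

_PHYLA = (
    "Proteobacteria",
    "Actinobacteria",
    "Acidobacteria",
    "Thermoproteota",
    "Verrucomicrobia",
    "Bacteroidetes",
    "Firmicutes",
)


def gen_annotations(
    n_genomes: int,
    role_probs: Mapping[str, float],
    phylum_profile: Mapping[str, float] | None = None,
    seed: int = 0,
    cfg: MarkerConfig | None = None,
    independent_alt_prob: float = 0.3,
    exact_counts: bool = False,
) -> tuple[list[GenomeAnnotation], SimulationTruth]:
    """Generate genomes whose marker sets force a sampled role.

    Roles are drawn from ``role_probs`` (multinomially, or as exact rounded
    counts when ``exact_counts`` is set, which makes planted proportions
    reproduce without sampling error). A producer receives >= 1 biosynthesis
    marker and >= 1 dependent function; a dependent >= 1 dependent function
    only; corrinoid-independent alternatives are sprinkled independently of
    role (they never change the rule-table outcome).
    """
    cfg = cfg or DEFAULT_MARKER_CONFIG
    missing = set(role_probs) - set(ROLES)
    if missing:
        raise ValueError(f"unknown roles in role_probs: {sorted(missing)}")
    probs = np.array([role_probs.get(r, 0.0) for r in ROLES], dtype=float)
    if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
        raise ValueError("role_probs must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    if exact_counts:
        counts = np.floor(probs * n_genomes).astype(int)
        # distribute the remainder to the largest fractional parts
        frac = probs * n_genomes - counts
        for i in np.argsort(frac)[::-1][: n_genomes - counts.sum()]:
            counts[i] += 1
        roles = np.repeat(ROLES, counts)
        rng.shuffle(roles)
    else:
        roles = rng.choice(ROLES, size=n_genomes, p=probs)

    phyla = list((phylum_profile or {p: 1 / len(_PHYLA) for p in _PHYLA}).keys())
    pweights = np.array(list((phylum_profile or {p: 1 for p in _PHYLA}).values()), float)
    pweights = pweights / pweights.sum()

    bio_markers = sorted(cfg.biosynthesis_markers)
    dep_fns = sorted(cfg.dependent_markers)
    genomes: list[GenomeAnnotation] = []
    truth_roles: dict[str, str] = {}
    for i in range(n_genomes):
        gid = f"MAG{i + 1:05d}"
        role = str(roles[i])
        detected: set[str] = set()
        if role in ("producer", "producer_non_user"):
            k = rng.integers(1, len(bio_markers) + 1)
            detected |= set(rng.choice(bio_markers, size=k, replace=False))
        if role in ("producer", "dependent"):
            k = rng.integers(1, len(dep_fns) + 1)
            for fn in rng.choice(dep_fns, size=k, replace=False):
                ids = sorted(cfg.dependent_markers[fn])
                detected.add(str(rng.choice(ids)))
        # independent alternatives never alter the role
        for fn in cfg.paired_functions():
            if rng.random() < independent_alt_prob:
                ids = sorted(cfg.independent_alternatives[fn])
                detected.add(str(rng.choice(ids)))
        phylum = str(rng.choice(phyla, p=pweights))
        domain = "archaea" if phylum == "Thermoproteota" else "bacteria"
        genomes.append(
            GenomeAnnotation(
                genome_id=gid,
                detected=frozenset(detected),
                domain=domain,
                lineage=(phylum, f"{phylum}_class", f"{phylum}_order",
                         f"{phylum}_family", f"{phylum}_genus"),
            )
        )
        truth_roles[gid] = role

    truth = SimulationTruth(
        scenario="annotations",
        seed=seed,
        params={
            "n_genomes": n_genomes,
            "role_probs": dict(role_probs),
            "roles": truth_roles,
            "exact_counts": exact_counts,
        },
    )
    return genomes, truth


def gen_study_annotation_standin(
    seed: int = 0, cfg: MarkerConfig | None = None
) -> tuple[list[GenomeAnnotation], SimulationTruth]:
    """SYNTHETIC stand-in for a 503-MAG soil annotation table.

    This is generated data, not a real survey table: it plants, exactly,
    the role breakdown and enzyme-redundancy structure observed in a
    grassland-soil MAG survey (398 dependents, 102 producers, 2 independents,
    1 producer/non-user; corrinoid-dependent epoxyqueuosine reductase in 307
    genomes with a single corrinoid-independent QueH; 45 genomes with both
    RNR classes and 231 of 420 RNR-detected genomes independent-only), so
    that the classifier and redundancy report can be exercised at study
    scale against known truth. Genome order and marker choices are seeded.

    The rule constraints are respected by construction: every dependent- or
    producer-role genome carries at least one corrinoid-dependent function,
    the three non-user genomes carry none, and corrinoid-independent
    alternatives are placed freely since they never alter the role.
    """
    cfg = cfg or DEFAULT_MARKER_CONFIG
    rng = np.random.default_rng(seed)
    n = 503
    role_counts = {"dependent": 398, "producer": 102, "independent": 2, "producer_non_user": 1}
    roles = np.repeat(list(role_counts), list(role_counts.values()))
    rng.shuffle(roles)
    users = np.flatnonzero(np.isin(roles, ("dependent", "producer")))
    non_users = np.flatnonzero(~np.isin(roles, ("dependent", "producer")))

    detected: list[set[str]] = [set() for _ in range(n)]
    bio = sorted(cfg.biosynthesis_markers)
    for i in np.flatnonzero(np.isin(roles, ("producer", "producer_non_user"))):
        k = rng.integers(1, len(bio) + 1)
        detected[i].update(rng.choice(bio, size=k, replace=False))

    def plant(indices: np.ndarray, n_pick: int, ids: frozenset[str]) -> np.ndarray:
        chosen = rng.choice(indices, size=n_pick, replace=False)
        for i in chosen:
            detected[i].add(str(rng.choice(sorted(ids))))
        return chosen

    # epoxyqueuosine reductase: 307 dependent-form users, one independent QueH
    queg_dep = plant(users, 307, cfg.dependent_markers["epoxyqueuosine_reductase"])
    queh_pool = np.setdiff1d(users, queg_dep)
    plant(queh_pool, 1, cfg.independent_alternatives["epoxyqueuosine_reductase"])

    # RNR: both=45, dependent-only=144 (users), independent-only=231
    rnr_dep = plant(users, 189, cfg.dependent_markers["ribonucleotide_reductase"])
    rnr_both = rng.choice(rnr_dep, size=45, replace=False)
    for i in rnr_both:
        detected[i].add(str(rng.choice(sorted(cfg.independent_alternatives["ribonucleotide_reductase"]))))
    rnr_indep_pool = np.concatenate([np.setdiff1d(users, rnr_dep), non_users])
    plant(rnr_indep_pool, 231, cfg.independent_alternatives["ribonucleotide_reductase"])

    # methionine synthase and MCM planted loosely (not pinned to a target)
    meth_dep = plant(users, 320, cfg.dependent_markers["methionine_synthase"])
    for i in rng.choice(meth_dep, size=138, replace=False):
        detected[i].add(str(rng.choice(sorted(cfg.independent_alternatives["methionine_synthase"]))))
    mcm_dep = plant(users, 250, cfg.dependent_markers["methylmalonyl_coa_mutase"])
    mcm_free = np.setdiff1d(users, mcm_dep)
    plant(mcm_free, min(111, mcm_free.size), cfg.independent_alternatives["methylmalonyl_coa_mutase"])

    # every user must carry >= 1 dependent function; fall back to MetH
    all_dep_ids = cfg.all_dependent_identifiers()
    for i in users:
        if not (detected[i] & all_dep_ids):
            detected[i].add(sorted(cfg.dependent_markers["methionine_synthase"])[0])

    phyla = list(_PHYLA)
    genomes = []
    for i in range(n):
        phylum = phyla[int(rng.integers(len(phyla)))]
        genomes.append(
            GenomeAnnotation(
                genome_id=f"SMAG{i + 1:04d}",
                detected=frozenset(detected[i]),
                domain="archaea" if phylum == "Thermoproteota" else "bacteria",
                lineage=(phylum, f"{phylum}_class", f"{phylum}_order",
                         f"{phylum}_family", f"{phylum}_genus"),
            )
        )
    truth = SimulationTruth(
        scenario="study_annotation_standin",
        seed=seed,
        params={
            "n_genomes": n,
            "role_counts": role_counts,
            "roles": {g.genome_id: str(r) for g, r in zip(genomes, roles)},
            "queg_dependent": 307,
            "queh_independent": 1,
            "rnr_both": 45,
            "rnr_dependent_only": 144,
            "rnr_independent_only": 231,
            "rnr_detected": 420,
        },
    )
    return genomes, truth


# ---------------------------------------------------------------------------
# extraction series
# ---------------------------------------------------------------------------


def gen_extraction_series(
    true_kd: float,
    initial_pool_pmol_per_g: float,
    geometry: ExtractionGeometry | None = None,
    n_rounds: int = 12,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[ExtractionSeries, SimulationTruth]:
    """Forward-simulate a serial extraction at a known K_d.

    The soil-phase pool (per gram) decays geometrically; the aqueous
    concentration at round n is K_d times the soil-phase molar
    concentration. Observed aqueous values carry multiplicative
    lognormal(0, noise_sd) noise. The truth records the noiseless series and
    the residual soil pool after the final round, so mass conservation
    (initial = sum removed + residual) is checkable exactly.
    """
    if true_kd < 0:
        raise ValueError("true_kd must be >= 0")
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    geometry = geometry or ExtractionGeometry()
    rng = np.random.default_rng(seed)

    # soil-phase molar concentration (nM over the soil volume)
    soil_conc_nM = (
        initial_pool_pmol_per_g * geometry.soil_mass / geometry.vol_soil
    ) / 1e3  # pmol/L -> nM
    ratio = geometry.vol_ratio
    shrink = 1.0 / (1.0 + true_kd * ratio)
    aq_true: list[float] = []
    for _ in range(n_rounds):
        soil_conc_nM *= shrink
        aq_true.append(true_kd * soil_conc_nM)
    noise = np.exp(rng.normal(0.0, noise_sd, size=n_rounds)) if noise_sd else np.ones(n_rounds)
    aq_obs = np.array(aq_true) * noise

    residual_pool = soil_conc_nM * geometry.vol_soil * 1e3 / geometry.soil_mass  # pmol/g
    rounds = tuple(
        ExtractionRound(n=i + 1, aq_conc=float(c)) for i, c in enumerate(aq_obs)
    )
    series = ExtractionSeries(rounds, geometry, residual_soil_conc=residual_pool)
    truth = SimulationTruth(
        scenario="extraction_series",
        seed=seed,
        params={
            "true_kd": true_kd,
            "initial_pool_pmol_per_g": initial_pool_pmol_per_g,
            "n_rounds": n_rounds,
            "noise_sd": noise_sd,
            "aq_true_nM": list(map(float, aq_true)),
            "residual_pool_pmol_per_g": float(residual_pool),
            "geometry": dataclasses.asdict(geometry),
        },
    )
    return series, truth


# ---------------------------------------------------------------------------
# community tables
# ---------------------------------------------------------------------------

_DESIGNS = {
    "enrichment": {
        "media": ("M9", "R2"),
        "timepoints": (1, 2, 12, 14),  # weeks
        "n_reps": 6,
        "uninoculated": True,
    },
    "microcosm": {
        "media": ("soil",),
        "timepoints": (0, 3, 10, 30, 50),  # days
        "n_reps": 5,
        "uninoculated": False,
    },
}


def _taxonomy_tree(n_taxa: int, rng: np.random.Generator) -> pd.DataFrame:
    """Hierarchical lineage for n zOTUs: nested labels so responder signal
    propagates coherently to higher ranks."""
    n_phyla = max(2, min(8, n_taxa // 12 + 2))
    rows = []
    for i in range(n_taxa):
        p = i % n_phyla
        c = i % (n_phyla * 2)
        o = i % max(2, n_taxa // 5)
        f = i % max(2, n_taxa // 3)
        g = i % max(2, int(n_taxa // 1.5))
        rows.append(
            {
                "phylum": f"p{p}",
                "class": f"c{c}",
                "order": f"o{o}",
                "family": f"f{f}",
                "genus": f"g{g}",
                "zotu": f"zotu{i + 1}",
            }
        )
    tax = pd.DataFrame(rows).set_index(pd.Index([r["zotu"] for r in rows], name="zotu_id"))
    return tax


def gen_community(
    design: str,
    n_taxa: int = 200,
    responders: Mapping[str, Mapping[str, float]] | None = None,
    depth: int = 20000,
    n_reps: int | None = None,
    timepoints: Sequence | None = None,
    media: Sequence[str] | None = None,
    baseline_sigma: float = 1.5,
    replicate_sigma: float = 0.2,
    overdispersion: float = 0.0,
    effect_timepoints: Sequence | None = None,
    baseline_shares: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[FeatureTable, SimulationTruth]:
    """Generate a treatment-structured zOTU count table with planted effects.

    Parameters
    ----------
    design
        ``"enrichment"`` or ``"microcosm"`` (sets media, replicate number,
        timepoints and uninoculated controls unless overridden).
    responders
        zOTU id -> {corrinoid: fold change} multiplying the taxon's expected
        relative abundance in that treatment before renormalisation;
        fold changes must be > 0 (FC < 1 models suppression).
    depth
        Multinomial sequencing depth per sample.
    baseline_sigma / replicate_sigma
        Lognormal sd of expected abundances across taxa / of per-replicate
        wobble around the treatment mean.
    overdispersion
        0 gives plain multinomial counts; > 0 draws per-sample proportions
        from a Dirichlet with concentration proportions/overdispersion.
    effect_timepoints
        Timepoints at which planted effects apply (default: all except an
        initial timepoint 0).
    baseline_shares
        zOTU id -> baseline relative abundance to pin exactly (the remaining
        mass is shared by the other taxa in their drawn proportions); lets a
        scenario plant a taxon at a known community share.
    """
    if design not in _DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected {sorted(_DESIGNS)}")
    spec = _DESIGNS[design]
    n_reps = n_reps if n_reps is not None else spec["n_reps"]
    timepoints = tuple(timepoints) if timepoints is not None else spec["timepoints"]
    media = tuple(media) if media is not None else spec["media"]
    responders = {k: dict(v) for k, v in (responders or {}).items()}
    if depth < n_taxa:
        import warnings

        warnings.warn(f"depth {depth} < n_taxa {n_taxa}: many taxa will be unobserved")

    rng = np.random.default_rng(seed)
    tax = _taxonomy_tree(n_taxa, rng)
    zotus = list(tax.index)
    bad = set(responders) - set(zotus)
    if bad:
        raise ValueError(f"responders not in taxon set: {sorted(bad)}")
    for z, fcs in responders.items():
        for cor, fc in fcs.items():
            if fc <= 0:
                raise ValueError(f"fold change for {z}/{cor} must be > 0, got {fc}")

    baseline = np.exp(rng.normal(0.0, baseline_sigma, size=n_taxa))
    baseline /= baseline.sum()
    if baseline_shares:
        bad_share = set(baseline_shares) - set(zotus)
        if bad_share:
            raise ValueError(f"baseline_shares not in taxon set: {sorted(bad_share)}")
        total_share = sum(baseline_shares.values())
        if not 0 < total_share < 1:
            raise ValueError("baseline_shares must sum to a value in (0, 1)")
        pinned = np.array([z in baseline_shares for z in zotus])
        baseline[~pinned] *= (1.0 - total_share) / baseline[~pinned].sum()
        for z, s in baseline_shares.items():
            baseline[zotus.index(z)] = s
    if effect_timepoints is None:
        effect_timepoints = tuple(t for t in timepoints if t != 0)
    effect_timepoints = set(effect_timepoints)

    counts: dict[str, np.ndarray] = {}
    meta_rows = []
    for medium in media:
        for tp in timepoints:
            for cor in CORRINOIDS:
                expected = baseline.copy()
                if tp in effect_timepoints:
                    for z, fcs in responders.items():
                        if cor in fcs:
                            expected[zotus.index(z)] *= fcs[cor]
                expected = expected / expected.sum()
                for rep in range(1, n_reps + 1):
                    sid = f"{medium}.{cor}.t{tp}.r{rep}"
                    wobble = np.exp(rng.normal(0.0, replicate_sigma, size=n_taxa))
                    p = expected * wobble
                    p /= p.sum()
                    if overdispersion > 0:
                        p = rng.dirichlet(p / overdispersion)
                    counts[sid] = rng.multinomial(depth, p)
                    meta_rows.append(
                        {
                            "sample_id": sid,
                            "medium": medium,
                            "corrinoid": cor,
                            "timepoint": tp,
                            "replicate": rep,
                            "inoculated": True,
                        }
                    )
            if spec["uninoculated"]:
                sid = f"{medium}.uninoculated.t{tp}"
                # sparse cross-contamination profile at low depth
                p = rng.dirichlet(np.full(n_taxa, 0.05))
                counts[sid] = rng.multinomial(max(200, depth // 20), p)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "medium": medium,
                        "corrinoid": "none",
                        "timepoint": tp,
                        "replicate": 0,
                        "inoculated": False,
                    }
                )

    count_frame = pd.DataFrame(counts, index=pd.Index(zotus, name="zotu_id"))
    # drop never-observed taxa? keep them: observed set is part of the truth,
    # but all-zero rows are legal for the table invariants (columns must sum > 0)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    table = FeatureTable(count_frame, meta, tax)
    truth = SimulationTruth(
        scenario=f"community_{design}",
        seed=seed,
        params={
            "design": design,
            "n_taxa": n_taxa,
            "responders": responders,
            "depth": depth,
            "n_reps": n_reps,
            "timepoints": list(timepoints),
            "media": list(media),
            "effect_timepoints": sorted(effect_timepoints),
            "baseline": baseline.tolist(),
            "overdispersion": overdispersion,
        },
    )
    return table, truth


# ---------------------------------------------------------------------------
# standard curves
# ---------------------------------------------------------------------------


def gen_standard_curve(
    od_min: float = 0.10,
    od_max: float = 0.85,
    ec50_nM: float = 0.08,
    hill: float = 1.0,
    saturation_conc: float = 1.0,
    concentrations: Sequence[float] | None = None,
    n_blanks: int = 6,
    blank_sd: float = 0.01,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate bioassay calibration data from a saturating logistic response.

    OD(c) = od_min + (od_max - od_min) * c^h / (EC50^h + c^h), evaluated on a
    log-spaced concentration grid up to ``saturation_conc`` (default 1 nM,
    where the assay plateaus). Returns a tidy frame with rows for blanks
    (concentration 0) and calibration points, plus the truth.
    """
    if od_max <= od_min:
        raise ValueError("od_max must exceed od_min (monotone saturating shape)")
    if hill <= 0 or ec50_nM <= 0:
        raise ValueError("hill and ec50 must be positive")
    rng = np.random.default_rng(seed)
    if concentrations is None:
        concentrations = np.logspace(-2, np.log10(saturation_conc), 7)
    concentrations = np.asarray(concentrations, float)

    def od(c: np.ndarray) -> np.ndarray:
        return od_min + (od_max - od_min) * c**hill / (ec50_nM**hill + c**hill)

    ods = od(concentrations)
    if noise:
        ods = ods * np.exp(rng.normal(0.0, noise, size=ods.size))
    blanks = od_min + rng.normal(0.0, blank_sd, size=n_blanks)
    rows = [{"conc_nM": 0.0, "od600": float(b)} for b in blanks]
    rows += [
        {"conc_nM": float(c), "od600": float(o)} for c, o in zip(concentrations, ods)
    ]
    frame = pd.DataFrame(rows)
    truth = SimulationTruth(
        scenario="standard_curve",
        seed=seed,
        params={
            "od_min": od_min,
            "od_max": od_max,
            "ec50_nM": ec50_nM,
            "hill": hill,
            "saturation_conc": saturation_conc,
            "concentrations": concentrations.tolist(),
            "true_od": od(concentrations).tolist(),
            "noise": noise,
        },
    )
    return frame, truth
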