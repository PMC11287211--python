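"""Corrinoid ecological role classification for genomes and MAGs.

Soil (and other) microbial genomes can be sorted into four ecological roles
with respect to corrinoid (vitamin B12 family) cofactors, based solely on
gene content:

* **producer** — encodes de novo corrin-ring biosynthesis *and* at least one
  corrinoid-dependent enzyme;
* **producer_non_user** — encodes biosynthesis but no corrinoid-dependent
  enzyme (a rarely observed, hard-to-verify category);
* **dependent** — encodes corrinoid-dependent enzymes but no biosynthesis,
  hence relies on externally supplied corrinoids;
* **independent** — encodes neither.

Biosynthesis capacity is inferred from marker genes for three corrin-ring
steps with anaerobic/aerobic orthologue pairs (cbiC/cobH, cbiF/cobM,
cbiL/cobI), whose presence is highly correlated with a complete de novo
pathway. Corrinoid-dependent functions are detected from KEGG orthologue
(KO) annotations, with one exception: the class II (corrinoid-dependent)
ribonucleotide reductase is detected via Pfam PF08471 because the KO K00525
conflates class I and class II RNRs.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "MarkerConfig",
    "GenomeAnnotation",
    "RoleAssignment",
    "ROLES",
    "classify_role",
    "classify_table",
    "redundancy_report",
    "DEFAULT_MARKER_CONFIG",
]

ROLES = ("producer", "dependent", "independent", "producer_non_user")

#: identifiers look like KO (K00548), Pfam (PF08471) or lowercase gene symbols
_IDENTIFIER_RE = re.compile(r"^(K\d{5}|PF\d{5}|[a-zA-Z][\w.\-]{1,31})$")

#: ranks used when parsing semicolon-delimited lineages
LINEAGE_RANKS = ("phylum", "class", "order", "family", "genus")


class AnnotationError(ValueError):
    """Malformed annotation input (identifiers, ids, duplicates)."""


class ConfigError(ValueError):
    """Marker configuration violates its invariants."""


@dataclass(frozen=True)
class MarkerConfig:
    """Identifier sets driving the role rule table.

    ``dependent_markers`` and ``independent_alternatives`` are keyed by
    function name; functions present in both maps are "paired" (a
    corrinoid-dependent enzyme with a known corrinoid-independent
    alternative) and drive :func:`redundancy_report`. Identifier lists are
    deliberately editable data, not code: the defaults cover the functions
    with well-established identifiers and are expected to be replaced by the
    user's own annotation vocabulary where it differs.
    """

    biosynthesis_markers: frozenset[str] = frozenset(
        {"K06042", "K05936", "K03394"}  # cbiC/cobH, cbiF/cobM, cbiL/cobI
    )
    dependent_markers: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: {
            "methionine_synthase": frozenset({"K00548"}),  # MetH
            "methylmalonyl_coa_mutase": frozenset({"K01847", "K01848", "K01849"}),
            "epoxyqueuosine_reductase": frozenset({"K18979"}),  # QueG
            # class II RNR via Pfam; K00525 conflates class I and II
            "ribonucleotide_reductase": frozenset({"PF08471"}),
        }
    )
    independent_alternatives: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: {
            "methionine_synthase": frozenset({"K00549"}),  # MetE
            "methylmalonyl_coa_mutase": frozenset({"K01659", "K01720", "K03417"}),
            "epoxyqueuosine_reductase": frozenset({"queH"}),
            "ribonucleotide_reductase": frozenset({"K00525", "K00526"}),  # class I
        }
    )

    def __post_init__(self) -> None:
        if not self.biosynthesis_markers:
            raise ConfigError("biosynthesis_markers must be nonempty")
        if "K00525" in self.all_dependent_identifiers():
            raise ConfigError(
                "K00525 conflates class I and class II RNRs and must not be a "
                "dependent marker; use PF08471 for the class II RNR"
            )
        for fn in self.paired_functions():
            overlap = self.dependent_markers[fn] & self.independent_alternatives[fn]
            if overlap:
                raise ConfigError(
                    f"function {fn!r}: identifiers {sorted(overlap)} appear in "
                    "both the dependent and independent set"
                )

    def paired_functions(self) -> tuple[str, ...]:
        return tuple(
            fn for fn in self.dependent_markers if fn in self.independent_alternatives
        )

    def all_dependent_identifiers(self) -> frozenset[str]:
        out: set[str] = set()
        for ids in self.dependent_markers.values():
            out |= ids
        return frozenset(out)


@dataclass(frozen=True)
class GenomeAnnotation:
    """One genome's detected annotation identifiers plus taxonomy."""

    genome_id: str
    detected: frozenset[str]
    domain: str = "bacteria"
    lineage: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise AnnotationError("empty genome_id")
        for ident in self.detected:
            if not _IDENTIFIER_RE.match(ident):
                raise AnnotationError(
                    f"genome {self.genome_id!r}: malformed identifier {ident!r}"
                )

    @property
    def phylum(self) -> str:
        return self.lineage[0] if self.lineage else "unassigned_phylum"


def parse_lineage(lineage: str, ranks: tuple[str, ...] = LINEAGE_RANKS) -> tuple[str, ...]:
    """Parse a semicolon-delimited lineage, padding missing ranks.

    Missing or blank ranks become ``unassigned_<rank>`` so per-rank
    marginals still sum over the full genome set.
    """
    parts = [p.strip() for p in str(lineage).split(";")] if lineage else []
    out = []
    for i, rank in enumerate(ranks):
        label = parts[i] if i < len(parts) and parts[i] else f"unassigned_{rank}"
        out.append(label)
    return tuple(out)


@dataclass(frozen=True)
class RoleAssignment:
    genome_id: str
    role: str
    n_biosynthesis_markers: int
    n_dependent_functions: int
    #: producer/non-user calls cannot be verified experimentally; flagged
    warning: str | None = None


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_role(genome: GenomeAnnotation, cfg: MarkerConfig | None = None) -> RoleAssignment:
    """Assign one of the four corrinoid ecological roles to a genome.

    The rule table is a total function of two booleans: whether at least one
    biosynthesis marker gene is detected, and whether at least one
    corrinoid-dependent function is detected.
    """
    cfg = cfg or DEFAULT_MARKER_CONFIG
    n_bio = len(genome.detected & cfg.biosynthesis_markers)
    n_dep = sum(1 for ids in cfg.dependent_markers.values() if genome.detected & ids)
    if n_bio > 0:
        role = "producer" if n_dep > 0 else "producer_non_user"
    else:
        role = "dependent" if n_dep > 0 else "independent"
    warning = (
        "producer_non_user calls cannot be verified from annotation alone"
        if role == "producer_non_user"
        else None
    )
    return RoleAssignment(genome.genome_id, role, n_bio, n_dep, warning)


def classify_table(
    genomes: Iterable[GenomeAnnotation], cfg: MarkerConfig | None = None
) -> tuple[list[RoleAssignment], pd.DataFrame]:
    """Classify every genome and tally roles overall, per phylum and per domain.

    Returns the per-genome assignments and a tidy summary frame with columns
    ``scope`` (overall / phylum / domain), ``group``, ``role``, ``count``.
    Counts within each scope sum to the number of input genomes.
    """
    genomes = list(genomes)
    if not genomes:
        raise AnnotationError("empty genome table")
    ids = [g.genome_id for g in genomes]
    dupes = sorted({i for i, c in Counter(ids).items() if c > 1})
    if dupes:
        raise AnnotationError(f"duplicate genome_id values: {dupes}")

    cfg = cfg or DEFAULT_MARKER_CONFIG
    assignments = [classify_role(g, cfg) for g in genomes]

    rows = []
    overall = Counter(a.role for a in assignments)
    for role in ROLES:
        rows.append(("overall", "all", role, overall.get(role, 0)))
    by_phylum: Counter = Counter((g.phylum, a.role) for g, a in zip(genomes, assignments))
    for (phylum, role), n in sorted(by_phylum.items()):
        rows.append(("phylum", phylum, role, n))
    by_domain: Counter = Counter((g.domain, a.role) for g, a in zip(genomes, assignments))
    for (domain, role), n in sorted(by_domain.items()):
        rows.append(("domain", domain, role, n))
    summary = pd.DataFrame(rows, columns=["scope", "group", "role", "count"])
    return assignments, summary


def role_percentages(summary: pd.DataFrame) -> dict[str, float]:
    """Overall role mix as percentages of the genome set."""
    overall = summary[summary["scope"] == "overall"].set_index("role")["count"]
    total = int(overall.sum())
    return {role: 100.0 * overall.get(role, 0) / total for role in ROLES}


# ---------------------------------------------------------------------------
# enzyme redundancy
# ---------------------------------------------------------------------------

REDUNDANCY_CATEGORIES = ("dependent_only", "independent_only", "both", "neither")


def redundancy_report(
    genomes: Iterable[GenomeAnnotation],
    cfg: MarkerConfig | None = None,
    functions: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Count, per paired function, genomes encoding the corrinoid-dependent
    enzyme, the corrinoid-independent alternative, both, or neither.

    The four categories partition the genome set for every function.
    Percentages are emitted over all genomes (``pct_all``) and over genomes
    in which the function was detected at all (``pct_detected``) — the latter
    is the denominator conventionally used for RNR statements.
    """
    genomes = list(genomes)
    cfg = cfg or DEFAULT_MARKER_CONFIG
    functions = tuple(functions) if functions is not None else cfg.paired_functions()
    for fn in functions:
        if fn not in cfg.dependent_markers or fn not in cfg.independent_alternatives:
            raise ConfigError(f"function {fn!r} is not a configured paired function")

    n_total = len(genomes)
    rows = []
    for fn in functions:
        dep_ids = cfg.dependent_markers[fn]
        ind_ids = cfg.independent_alternatives[fn]
        counts = Counter()
        for g in genomes:
            has_dep = bool(g.detected & dep_ids)
            has_ind = bool(g.detected & ind_ids)
            if has_dep and has_ind:
                counts["both"] += 1
            elif has_dep:
                counts["dependent_only"] += 1
            elif has_ind:
                counts["independent_only"] += 1
            else:
                counts["neither"] += 1
        n_detected = n_total - counts["neither"]
        for cat in REDUNDANCY_CATEGORIES:
            n = counts.get(cat, 0)
            rows.append(
                {
                    "function": fn,
                    "category": cat,
                    "count": n,
                    "pct_all": 100.0 * n / n_total if n_total else 0.0,
                    "pct_detected": (100.0 * n / n_detected) if n_detected else float("nan"),
                }
            )
    return pd.DataFrame(rows)


DEFAULT_MARKER_CONFIG = MarkerConfig()
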