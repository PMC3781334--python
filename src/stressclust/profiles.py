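"""Categorical expression profiles and the named group taxonomy.

Each gene's behavior over the four canonical comparisons is an ordered
4-tuple of three-state calls — one of 3^4 = 81 possible profiles.  Genes
whose fourth comparison (KO-TM vs WT-TM at the late time point) is
"unchanged" are unlikely contributors to the genotype-dependent phenotype
and are filtered out, leaving 3x3x3x2 = 54 admissible profiles.  The most
populated profiles carry the letter names A-I, plus the profile expected of
direct ATF6 targets (induced in WT at both times, blunted in the knockout).

Group G and H tuples are inferred (G by symmetry with I among the
down-groups, H as the sustained-up profile among the up-groups) and carry an
``inferred`` flag in every output; both are overridable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calls import CALL_LEVELS, DOWN, UNCHANGED, UP, CALL_ALPHA, FOLD_THRESHOLD_LOG2
from .errors import StressclustError
from .io import select_samples

logger = logging.getLogger(__name__)

Profile = tuple[str, str, str, str]

COMPARISON_NAMES = ("c1", "c2", "c3", "c4")

NC = UNCHANGED  # shorthand used in taxonomy literals

DEFAULT_GROUP_PROFILES: dict[str, Profile] = {
    "A": (NC, NC, NC, UP),
    "B": (NC, NC, NC, DOWN),
    "C": (UP, NC, NC, UP),
    "D": (DOWN, NC, NC, DOWN),
    "E": (UP, NC, UP, UP),
    "F": (DOWN, NC, DOWN, DOWN),
    "G": (NC, NC, DOWN, DOWN),
    "H": (UP, UP, UP, UP),
    "I": (NC, NC, UP, UP),
    "ATF6": (UP, DOWN, UP, DOWN),
}

#: labels whose profile tuples are inferred rather than explicitly published.
INFERRED_LABELS = frozenset({"G", "H"})


@dataclass(frozen=True)
class GroupTaxonomy:
    """Injective mapping from named groups to expression profiles."""

    profiles: dict[str, Profile] = field(default_factory=lambda: dict(DEFAULT_GROUP_PROFILES))
    inferred: frozenset = INFERRED_LABELS

    def __post_init__(self):
        seen: dict[Profile, str] = {}
        for label, prof in self.profiles.items():
            if len(prof) != 4 or any(c not in CALL_LEVELS for c in prof):
                raise StressclustError(f"taxonomy {label}: invalid profile {prof}")
            if prof in seen:
                raise StressclustError(
                    f"taxonomy not injective: {label} and {seen[prof]} share {prof}")
            seen[prof] = label

    def label_of(self, profile: Profile) -> str | None:
        for label, prof in self.profiles.items():
            if prof == tuple(profile):
                return label
        return None


def all_profiles() -> list[Profile]:
    """Enumerate all 81 three-state 4-tuples (down < unchanged < up order)."""
    return list(itertools.product(CALL_LEVELS, repeat=4))


def regulated_profiles() -> list[Profile]:
    """The 54 profiles whose c4 call is not 'unchanged'."""
    return [p for p in all_profiles() if p[3] != UNCHANGED]


def profile_id(profile: Profile) -> str:
    """Compact string form, e.g. 'down/nc/down/down'."""
    return "/".join("nc" if c == UNCHANGED else c for c in profile)


def assign_profiles(calls: pd.DataFrame) -> pd.DataFrame:
    """Pivot tidy per-comparison calls into one 4-tuple profile per gene.

    ``calls`` must carry columns (gene, comparison, call) with the four
    canonical comparison names present for every gene.
    """
    wide = calls.pivot(index="gene", columns="comparison", values="call")
    for name in COMPARISON_NAMES:
        if name not in wide.columns:
            raise StressclustError(f"missing comparison {name!r} in calls")
        if wide[name].isna().any():
            gene = wide.index[wide[name].isna()][0]
            raise StressclustError(f"gene {gene!r}: missing call for comparison {name!r}")
    return wide[list(COMPARISON_NAMES)]


def _profile_sort_key(profile: Profile):
    order = {c: i for i, c in enumerate(CALL_LEVELS)}
    n_regulated = sum(c != UNCHANGED for c in profile)
    return (-n_regulated, tuple(order[c] for c in profile))


def collapse_probesets(profiles: pd.DataFrame, probeset_map: pd.Series) -> pd.DataFrame:
    """Collapse per-probeset profiles to one modal profile per gene.

    Ties are broken by (i) the profile with more regulated (non-unchanged)
    calls, then (ii) lexicographic order with down < unchanged < up per
    position.  Probesets absent from the map pass through under their own
    identifier with a warning.
    """
    genes = []
    for ps in profiles.index:
        if ps in probeset_map.index:
            genes.append(probeset_map[ps])
        else:
            logger.warning("probeset %s unmapped; passed through as its own gene", ps)
            genes.append(ps)
    tuples = [tuple(row) for row in profiles.to_numpy()]
    df = pd.DataFrame({"gene": genes, "profile": tuples})
    collapsed = {}
    for gene, grp in df.groupby("gene", sort=False):
        counts = grp["profile"].value_counts()
        top = counts[counts == counts.max()].index.tolist()
        if len(top) > 1:
            top.sort(key=_profile_sort_key)
            logger.info("gene %s: probeset profile tie broken to %s", gene, top[0])
        collapsed[gene] = top[0]
    out = pd.DataFrame.from_dict(collapsed, orient="index",
                                 columns=list(COMPARISON_NAMES))
    out.index.name = "gene"
    return out


def label_groups(profiles: pd.DataFrame,
                 taxonomy: GroupTaxonomy | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Attach group labels to per-gene profiles and tally membership.

    Returns ``(table, counts)``.  The table has columns c1..c4, profile_id,
    group (None for profiles outside the taxonomy or filtered by the c4
    criterion) and an ``inferred`` flag for labels whose defining tuple is
    an inference.  Counts are per label, largest first; unlabeled genes that
    survive the c4 filter are tallied under their raw profile id so the full
    54-way breakdown is always available.
    """
    if taxonomy is None:
        taxonomy = GroupTaxonomy()
    rows = []
    for gene, row in profiles.iterrows():
        prof = tuple(row[list(COMPARISON_NAMES)])
        label = taxonomy.label_of(prof)
        if label is None and prof[3] != UNCHANGED:
            tally_key = profile_id(prof)
        elif label is not None:
            tally_key = label
        else:
            tally_key = None  # filtered by criterion 4
        rows.append({"gene": gene, **dict(zip(COMPARISON_NAMES, prof)),
                     "profile_id": profile_id(prof), "group": label,
                     "tally": tally_key,
                     "inferred": label in taxonomy.inferred if label else False})
    table = pd.DataFrame(rows).set_index("gene")
    counts = (table["tally"].dropna().value_counts())
    counts.name = "n_genes"
    return table.drop(columns="tally"), counts


def build_heatmap_matrix(matrix: pd.DataFrame, samples: pd.DataFrame,
                         tau: float = FOLD_THRESHOLD_LOG2,
                         alpha: float = CALL_ALPHA,
                         calls: pd.DataFrame | None = None) -> pd.DataFrame:
    """Replicate-averaged log2-ratio matrix for display, filtered on the calls.

    Every column is expressed relative to vehicle-treated WT at its own time
    point (so the KO columns compound the WT effect and the genotype
    difference), column order WT_8h, KO_8h, WT_34h, KO_34h.  Rows are
    restricted to genes passing at least one of the four call criteria at
    (tau, alpha).  Note the deliberate difference of reference: the c2/c4
    call criteria compare KO-TM against WT-TM, whereas these display columns
    are all anchored on WT-vehicle.
    """
    from .calls import call_comparisons

    cols = {}
    for time, tag in ((8, "8h"), (34, "34h")):
        den = select_samples(samples, genotype="WT", treatment="vehicle", time=time)
        for geno in ("WT", "KO"):
            num = select_samples(samples, genotype=geno, treatment="TM", time=time)
            if not num or not den:
                raise StressclustError(f"missing condition group {geno}-TM/{time}h")
            cols[f"{geno}_{tag}"] = np.log2(
                matrix[num].mean(axis=1) / matrix[den].mean(axis=1))
    heat = pd.DataFrame(cols)[["WT_8h", "KO_8h", "WT_34h", "KO_34h"]]
    if calls is None:
        calls = call_comparisons(matrix, samples, tau=tau, alpha=alpha)
    passing = (calls[calls["call"] != UNCHANGED]["gene"]).unique()
    return heat.loc[heat.index.intersection(passing, sort=False)]
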