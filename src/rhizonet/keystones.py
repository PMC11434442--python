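"""Keystone identification, functional classification, and group statistics.

Keystones are nodes passing five strict centrality criteria (high degree,
weighted degree, closeness and clustering; low betweenness). Functional
categories are assigned from a taxon x EC gene-presence table: a taxon
belongs to a category when it carries at least one of the category's
enzymes. Group comparisons use fixed-effects ANOVA with explicit sums of
squares plus Tukey HSD with a compact letter display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from rhizonet.datasets import AbundanceTable, SampleMetadata
from rhizonet.errors import InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KeystoneCriteria:
    """Strict thresholds: four lower bounds (>) and one upper bound (<)."""

    min_degree: float = 6.0
    min_weighted_degree: float = 6.0
    min_closeness: float = 0.14
    min_clustering: float = 0.09
    max_betweenness: float = 0.05


def identify_keystones(
    metrics: pd.DataFrame, criteria: KeystoneCriteria | None = None
) -> pd.DataFrame:
    """Rows of ``metrics`` satisfying all five strict inequalities."""
    if criteria is None:
        criteria = KeystoneCriteria()
    required = ["degree", "weighted_degree", "closeness", "betweenness", "clustering"]
    for col in required:
        if col not in metrics.columns:
            raise ValidationError(f"metrics table missing column {col!r}")
        bad = metrics.index[metrics[col].isna()]
        if len(bad):
            raise ValidationError(f"missing {col} for node(s): {list(bad[:5])}")
    mask = (
        (metrics["degree"] > criteria.min_degree)
        & (metrics["weighted_degree"] > criteria.min_weighted_degree)
        & (metrics["closeness"] > criteria.min_closeness)
        & (metrics["clustering"] > criteria.min_clustering)
        & (metrics["betweenness"] < criteria.max_betweenness)
    )
    return metrics[mask].copy()


# ---------------------------------------------------------------------------
# Functional categories

#: Category -> list of (enzyme name, EC number). The C/N cycling enzyme has
#: no universally fixed EC; 3.2.1.52 is the conventional assignment and can
#: be overridden when building a catalog.
DEFAULT_CATEGORY_ENZYMES: dict[str, list[tuple[str, str]]] = {
    "stress": [("indolepyruvate decarboxylase", "4.1.1.74")],
    "siderophore": [("isochorismate synthase", "5.4.4.2")],
    "P decomposition": [("alkaline phosphatase", "3.1.3.1")],
    "N decomposition": [
        ("leucyl aminopeptidase", "3.4.11.1"),
        ("urease", "3.5.1.5"),
        ("amidase", "3.5.1.4"),
    ],
    "dissimilatory nitrate reduction": [("nitrite reductase", "1.7.2.2")],
    "C/N cycling": [("N-acetyl-B-glycosaminidase", "3.2.1.52")],
    "C decomposition": [
        ("alpha-glucosidase", "3.2.1.20"),
        ("beta-glucosidase", "3.2.1.21"),
    ],
    "biocontrol": [("S,S-butanediol dehydrogenase", "1.1.1.76")],
    "assimilatory nitrate reduction": [("ferredoxin-nitrite reductase", "1.7.7.1")],
}


@dataclass(frozen=True)
class FunctionCatalog:
    """EC -> functional category mapping plus the gene-presence matrix."""

    category_enzymes: dict = field(
        default_factory=lambda: {
            k: list(v) for k, v in DEFAULT_CATEGORY_ENZYMES.items()
        }
    )

    @property
    def ec_to_category(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for category, enzymes in self.category_enzymes.items():
            for _, ec in enzymes:
                out[ec] = category
        return out

    @property
    def all_ecs(self) -> list[str]:
        return list(self.ec_to_category)


def classify_functions(
    taxa,
    gene_presence: pd.DataFrame,
    catalog: FunctionCatalog | None = None,
) -> dict[str, set]:
    """Map each taxon to the functional categories it carries.

    ``gene_presence`` is taxon x EC, numeric copy numbers or indicators;
    presence means >= 1. Taxa absent from the table get an empty set with a
    warning. EC columns not in the catalog raise a validation error.
    """
    if catalog is None:
        catalog = FunctionCatalog()
    ec_map = catalog.ec_to_category
    unknown = [ec for ec in gene_presence.columns if ec not in ec_map]
    if unknown:
        raise ValidationError(f"unknown EC number(s) in gene-presence table: {unknown}")
    result: dict[str, set] = {}
    missing = []
    for taxon in taxa:
        if taxon not in gene_presence.index:
            missing.append(taxon)
            result[taxon] = set()
            continue
        row = gene_presence.loc[taxon]
        result[taxon] = {ec_map[ec] for ec in gene_presence.columns if row[ec] >= 1}
    if missing:
        logger.warning(
            "classify_functions: %d taxa absent from gene-presence table", len(missing)
        )
    return result


# ---------------------------------------------------------------------------
# Keystone abundance summaries


def keystone_abundance_by_group(
    table: AbundanceTable,
    metadata: SampleMetadata,
    keystones,
    group_col: str = "domestication_group",
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample summed keystone relative abundance and per-group mean +/- SE."""
    unknown = [k for k in keystones if k not in table.taxon_ids]
    if unknown:
        raise ValidationError(f"keystone ids not in abundance table: {unknown[:5]}")
    metadata.require(table.sample_ids)
    rel = table.to_relative()
    per_sample = (
        rel[list(keystones)].sum(axis=1)
        if len(list(keystones))
        else pd.Series(0.0, index=rel.index)
    )
    per_sample.name = "keystone_rel_abundance"
    groups = metadata.frame.loc[per_sample.index, group_col]
    rows = []
    for level, values in per_sample.groupby(groups):
        if len(values) < 2:
            raise InsufficientDataError(
                f"group {level!r} has {len(values)} sample(s); SE undefined"
            )
        rows.append(
            {
                "group": level,
                "n": len(values),
                "mean": values.mean(),
                "se": values.std(ddof=1) / np.sqrt(len(values)),
            }
        )
    summary = pd.DataFrame(rows).set_index("group")
    return per_sample, summary


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD


@dataclass(frozen=True)
class GroupTestResult:
    anova: pd.DataFrame  # rows: effects; columns: df, ss, ms, F, p
    tukey: pd.DataFrame  # pairwise comparisons with adjusted p
    letters: dict  # group level -> letter string


def _one_way_ss(values: np.ndarray, labels: np.ndarray):
    grand = values.mean()
    ss_total = float(((values - grand) ** 2).sum())
    ss_between = 0.0
    for level in np.unique(labels):
        group = values[labels == level]
        ss_between += len(group) * (group.mean() - grand) ** 2
    return ss_between, ss_total - ss_between


def _anova_one_way(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    levels = np.unique(labels)
    k = len(levels)
    n = len(values)
    ss_b, ss_w = _one_way_ss(values, labels)
    df_b, df_w = k - 1, n - k
    ms_b = ss_b / df_b
    ms_w = ss_w / df_w if df_w > 0 else np.nan
    f = ms_b / ms_w if ms_w > 0 else (0.0 if ms_b == 0 else np.inf)
    p = float(stats.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return pd.DataFrame(
        {
            "df": [df_b, df_w],
            "ss": [ss_b, ss_w],
            "ms": [ms_b, ms_w],
            "F": [f, np.nan],
            "p": [p, np.nan],
        },
        index=["group", "residual"],
    )


def _anova_two_way(values: np.ndarray, a: np.ndarray, b: np.ndarray) -> pd.DataFrame:
    """Balanced two-way fixed-effects ANOVA from explicit sums of squares."""
    grand = values.mean()
    a_levels, b_levels = np.unique(a), np.unique(b)
    ss_a = sum(
        (a == la).sum() * (values[a == la].mean() - grand) ** 2 for la in a_levels
    )
    ss_b = sum(
        (b == lb).sum() * (values[b == lb].mean() - grand) ** 2 for lb in b_levels
    )
    ss_cells = 0.0
    ss_error = 0.0
    for la in a_levels:
        for lb in b_levels:
            cell = values[(a == la) & (b == lb)]
            ss_cells += len(cell) * (cell.mean() - grand) ** 2
            ss_error += float(((cell - cell.mean()) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_err = len(values) - len(a_levels) * len(b_levels)
    ms_err = ss_error / df_err if df_err > 0 else np.nan
    rows = []
    for name, ss, df in (
        ("domestication", ss_a, df_a),
        ("fertilization", ss_b, df_b),
        ("interaction", ss_ab, df_ab),
    ):
        ms = ss / df if df > 0 else np.nan
        f = ms / ms_err if ms_err and ms_err > 0 else (0.0 if ms == 0 else np.inf)
        p = float(stats.f.sf(f, df, df_err)) if np.isfinite(f) else 0.0
        rows.append((name, df, ss, ms, f, p))
    rows.append(("residual", df_err, ss_error, ms_err, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["effect", "df", "ss", "ms", "F", "p"]
    ).set_index("effect")


def tukey_hsd(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons via the studentized-range distribution.

    Uses the Tukey-Kramer standard error so mildly unbalanced one-way data
    are handled; adjusted p is studentized_range.sf(q, k, df_error).
    """
    levels = sorted(np.unique(labels))
    k = len(levels)
    n = len(values)
    _, ss_w = _one_way_ss(values, labels)
    df_err = n - k
    mse = ss_w / df_err
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            gi = values[labels == levels[i]]
            gj = values[labels == levels[j]]
            diff = gi.mean() - gj.mean()
            se = np.sqrt(mse / 2.0 * (1.0 / len(gi) + 1.0 / len(gj)))
            if se == 0:
                q = 0.0 if diff == 0 else np.inf
            else:
                q = abs(diff) / se
            p = (
                float(stats.studentized_range.sf(q, k, df_err))
                if np.isfinite(q)
                else 0.0
            )
            rows.append((levels[i], levels[j], diff, se, q, min(p, 1.0)))
    return pd.DataFrame(
        rows, columns=["level_1", "level_2", "diff", "se", "q", "p_adj"]
    )


def compact_letters(tukey: pd.DataFrame, levels, alpha: float = 0.05) -> dict:
    """Compact letter display by insert-and-absorb.

    Two levels share a letter iff their adjusted p >= alpha.
    """
    levels = list(levels)
    letter_sets: list[set] = [set(levels)]
    for row in tukey.itertuples(index=False):
        if row.p_adj >= alpha:
            continue
        a, b = row.level_1, row.level_2
        for s in [s for s in letter_sets if a in s and b in s]:
            letter_sets.remove(s)
            s1, s2 = s - {a}, s - {b}
            for cand in (s1, s2):
                if not any(cand <= other for other in letter_sets):
                    letter_sets.append(cand)
    letter_sets = [s for s in letter_sets if s]
    # deterministic letter order: sets sorted by their smallest member
    letter_sets.sort(key=lambda s: sorted(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {level: "" for level in levels}
    for letter, s in zip(alphabet, letter_sets):
        for level in levels:
            if level in s:
                out[level] += letter
    return out


def anova_tukey(
    values: pd.Series,
    metadata: SampleMetadata,
    design: str = "one-way",
    factor: str = "domestication_group",
    alpha: float = 0.05,
) -> GroupTestResult:
    """Fixed-effects ANOVA plus Tukey HSD on per-sample values.

    ``design`` is "one-way" (on ``factor``) or "two-way" (domestication x
    fertilization; requires a balanced design, otherwise falls back to
    one-way per factor with a warning). Tukey comparisons and letters are
    reported for ``factor`` in both designs.
    """
    metadata.require(values.index)
    meta = metadata.frame.loc[values.index]
    y = values.to_numpy(dtype=float)
    labels = meta[factor].to_numpy()
    if len(np.unique(labels)) < 2:
        raise InsufficientDataError("need >= 2 groups for ANOVA")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise InsufficientDataError("every group needs >= 2 replicates")

    if design == "two-way":
        a = meta["domestication_group"].to_numpy()
        b = meta["fertilization"].to_numpy()
        cell_counts = meta.groupby(
            ["domestication_group", "fertilization"], observed=True
        ).size()
        if cell_counts.nunique() != 1:
            logger.warning(
                "unbalanced two-way design; falling back to one-way on %s", factor
            )
            anova = _anova_one_way(y, labels)
        else:
            anova = _anova_two_way(y, a, b)
    elif design == "one-way":
        anova = _anova_one_way(y, labels)
    else:
        raise ValueError(f"unknown design: {design!r}")

    tukey = tukey_hsd(y, labels)
    letters = compact_letters(tukey, sorted(np.unique(labels)), alpha=alpha)
    return GroupTestResult(anova=anova, tukey=tukey, letters=letters)
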