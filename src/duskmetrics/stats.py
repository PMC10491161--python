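"""Group-comparison statistics for behavioral metrics.

The scheme follows standard practice for multi-genotype fly behavior designs:
each experimental group (GAL4>UAS) is compared only against its genetic
controls (GAL4/+ and UAS/+) — planned comparisons, not all pairs.  Normally
distributed metrics use one-way ANOVA with Bonferroni-adjusted pooled-variance
post-hoc t tests; non-normal metrics use Kruskal-Wallis with tie-corrected
Dunn's post-hoc z tests, Bonferroni-adjusted over the planned comparisons.
Normality is gated per group by Shapiro-Wilk at alpha = 0.05, with an
override flag for metrics that should always be treated as non-normal
(sleep onset, whose distribution is floored at dusk).

An experimental group's phenotype "verdict" requires an adjusted p below
alpha against BOTH of its controls with agreeing effect directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

EXPERIMENTAL = "experimental"
CONTROL = "control"


@dataclass
class Group:
    label: str
    role: str  # EXPERIMENTAL or CONTROL
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.role not in (EXPERIMENTAL, CONTROL):
            raise ValueError(f"role must be experimental/control, got {self.role!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.label!r} contains non-finite values")
        if len(self.values) == 0:
            raise ValueError(f"group {self.label!r} is empty")


@dataclass
class GroupDesign:
    """Groups plus the planned experimental-vs-control comparison structure."""

    groups: list[Group]

    def __post_init__(self) -> None:
        roles = {g.role for g in self.groups}
        if EXPERIMENTAL not in roles or CONTROL not in roles:
            raise ValueError("design needs at least one experimental and one control group")

    @property
    def planned_pairs(self) -> list[tuple[str, str]]:
        return [
            (e.label, c.label)
            for e in self.groups
            if e.role == EXPERIMENTAL
            for c in self.groups
            if c.role == CONTROL
        ]

    def group(self, label: str) -> Group:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(label)


@dataclass
class PosthocRow:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_adj: float
    significant: bool
    direction: int  # sign of (experimental - control) location


@dataclass
class StatReport:
    omnibus_test: str
    omnibus_statistic: float
    omnibus_df: tuple
    omnibus_p: float
    posthoc: list[PosthocRow]
    alpha: float
    correction: str
    decision_trail: list[str] = field(default_factory=list)

    def row(self, pair: tuple[str, str]) -> PosthocRow:
        for r in self.posthoc:
            if r.pair == pair:
                return r
        raise KeyError(pair)

    def significance_stars(self) -> str:
        """Figure-legend style text block (*, P<0.05; **, P<0.01; ***, P<0.001; ns)."""
        lines = []
        for r in self.posthoc:
            p = r.p_adj
            stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else "ns"
            lines.append(f"{r.pair[0]} vs {r.pair[1]}: {stars} (adj. P = {p:.3g})")
        return "\n".join(lines)


def _bonferroni(p_raw: float, m: int) -> float:
    return min(1.0, m * p_raw)


def anova_bonferroni(design: GroupDesign, alpha: float = 0.05) -> StatReport:
    """One-way ANOVA with Bonferroni-adjusted pooled-variance post-hoc t tests.

    Pairwise t statistics use the ANOVA residual mean square and its N - k
    degrees of freedom (the classic Bonferroni multiple-comparison test);
    raw p values are multiplied by the number of planned comparisons.
    """
    values = [g.values for g in design.groups]
    for g in design.groups:
        if len(g.values) < 2:
            raise ValueError(f"group {g.label!r} needs n >= 2")
    n_total = sum(len(v) for v in values)
    k = len(values)
    df_within = n_total - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in values) / df_within
    if mse > 0:
        f_stat, f_p = sps.f_oneway(*values)
    else:  # all groups constant: no variance to explain
        f_stat, f_p = 0.0, 1.0
    pairs = design.planned_pairs
    m = len(pairs)
    rows = []
    for e_label, c_label in pairs:
        e, c = design.group(e_label), design.group(c_label)
        diff = e.values.mean() - c.values.mean()
        se = np.sqrt(mse * (1.0 / len(e.values) + 1.0 / len(c.values)))
        if se == 0:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
            p_raw = 1.0 if diff == 0 else 0.0
        else:
            t = diff / se
            p_raw = 2.0 * sps.t.sf(abs(t), df_within)
        p_adj = _bonferroni(p_raw, m)
        rows.append(
            PosthocRow((e_label, c_label), float(t), float(p_raw), float(p_adj),
                       p_adj < alpha, int(np.sign(diff)))
        )
    return StatReport(
        "one-way ANOVA", float(f_stat), (k - 1, df_within), float(f_p),
        rows, alpha, "Bonferroni",
    )


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float((counts**3 - counts).sum())


def kruskal_dunn(design: GroupDesign, alpha: float = 0.05) -> StatReport:
    """Kruskal-Wallis omnibus with Dunn's post-hoc z tests (tie-corrected).

    Dunn's z for a pair uses the pooled rank variance
    N(N+1)/12 - T/(12(N-1)), T = sum(t^3 - t) over tie groups; p values are
    two-sided normal and Bonferroni-adjusted over the planned comparisons.
    """
    values = [g.values for g in design.groups]
    for g in design.groups:
        if len(g.values) < 2:
            raise ValueError(f"group {g.label!r} needs n >= 2")
    pooled = np.concatenate(values)
    n_total = len(pooled)
    if np.ptp(pooled) == 0:  # all observations tied: H = 0 by convention
        h_stat, h_p = 0.0, 1.0
    else:
        h_stat, h_p = sps.kruskal(*values)
    ranks = sps.rankdata(pooled)
    mean_ranks, offset = {}, 0
    for g in design.groups:
        mean_ranks[g.label] = ranks[offset : offset + len(g.values)].mean()
        offset += len(g.values)
    tie = _tie_term(pooled)
    rank_var = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))
    pairs = design.planned_pairs
    m = len(pairs)
    rows = []
    for e_label, c_label in pairs:
        ne, nc = len(design.group(e_label).values), len(design.group(c_label).values)
        diff = mean_ranks[e_label] - mean_ranks[c_label]
        se = np.sqrt(rank_var * (1.0 / ne + 1.0 / nc))
        if se == 0:
            z, p_raw = 0.0, 1.0
        else:
            z = diff / se
            p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = _bonferroni(p_raw, m)
        rows.append(
            PosthocRow((e_label, c_label), float(z), float(p_raw), float(p_adj),
                       p_adj < alpha, int(np.sign(diff)))
        )
    return StatReport(
        "Kruskal-Wallis", float(h_stat), (len(values) - 1,), float(h_p),
        rows, alpha, "Bonferroni (Dunn)",
    )


def choose_test(
    design: GroupDesign,
    force_nonparametric: bool = False,
    normality_alpha: float = 0.05,
) -> tuple[str, list[str]]:
    """Pick the parametric or nonparametric branch, with a decision trail.

    Shapiro-Wilk is run per group at ``normality_alpha``; any rejection (or
    any group too small to test, n < 3, or with zero variance) routes to the
    nonparametric branch.  ``force_nonparametric`` overrides everything —
    used for sleep onset, which is floored at dusk.
    """
    trail: list[str] = []
    if force_nonparametric:
        trail.append("forced nonparametric by caller override")
        return "kruskal_dunn", trail
    for g in design.groups:
        if len(g.values) < 3:
            trail.append(f"{g.label}: n={len(g.values)} < 3, normality untestable -> nonparametric")
            return "kruskal_dunn", trail
        if np.ptp(g.values) == 0:
            trail.append(f"{g.label}: zero variance -> nonparametric")
            return "kruskal_dunn", trail
        w, p = sps.shapiro(g.values)
        trail.append(f"{g.label}: Shapiro-Wilk W={w:.4f}, p={p:.4g}")
        if p < normality_alpha:
            trail.append(f"{g.label}: normality rejected at alpha={normality_alpha}")
            return "kruskal_dunn", trail
    trail.append("all groups consistent with normality -> parametric")
    return "anova_bonferroni", trail


def run_comparison(
    design: GroupDesign,
    force_nonparametric: bool = False,
    alpha: float = 0.05,
) -> StatReport:
    """choose_test + the chosen omnibus/post-hoc, decision trail attached."""
    branch, trail = choose_test(design, force_nonparametric)
    fn = kruskal_dunn if branch == "kruskal_dunn" else anova_bonferroni
    report = fn(design, alpha)
    report.decision_trail = trail + report.decision_trail
    return report


@dataclass
class Verdict:
    experimental: str
    significant: bool
    reasons: list[str]


def vs_both_controls(report: StatReport, design: GroupDesign) -> dict[str, Verdict]:
    """Per-experimental verdict: significant vs BOTH controls, directions agreeing."""
    verdicts = {}
    controls = [g.label for g in design.groups if g.role == CONTROL]
    for g in design.groups:
        if g.role != EXPERIMENTAL:
            continue
        reasons = []
        try:
            rows = [report.row((g.label, c)) for c in controls]
        except KeyError as missing:
            raise ValueError(f"incomplete design: comparison {missing} absent from report")
        all_sig = all(r.significant for r in rows)
        directions = {r.direction for r in rows}
        same_dir = len(directions) == 1 and 0 not in directions
        for r in rows:
            reasons.append(
                f"vs {r.pair[1]}: adj. p={r.p_adj:.3g} "
                f"({'sig' if r.significant else 'ns'}), direction {r.direction:+d}"
            )
        verdicts[g.label] = Verdict(g.label, all_sig and same_dir, reasons)
    return verdicts
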