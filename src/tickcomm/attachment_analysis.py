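"""Attachment-site contingency analysis: does co-infestation move ticks?

Cattle tick taxa have evolved attachment preferences on the host body:
*Rhipicephalus spp* (excluding the *Boophilus* subgenus) attaches mostly on
the head and legs, while *A. variegatum*, *Hyalomma spp* and the *Boophilus*
species favour the trunk (flank, perineum).  Per site and ordered pair of
taxa, a 2 x C contingency table is built whose columns describe where the
focal taxon's individual ticks attached (C = 5 body parts, or C = 2 after
collapsing into preferred / not-preferred, the tail counting as
not-preferred) and whose rows split those ticks by whether their host
steer-month also carried the partner taxon.  Independence is tested with
Fisher's exact test (full enumeration over tables with the observed margins
where feasible, margin-preserving Monte-Carlo otherwise), and per-site
p-values are combined across sites with Stouffer's method — suited to a
small number of p-values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .survey_io import BODY_PARTS, SurveyTable

#: Body parts each taxon prefers; everything else (including the tail) is
#: "not preferred" under the 2-column coding.
PREFERRED_PARTS = {"RHIPICEPHALUS_SPP": ("head", "legs")}
DEFAULT_PREFERRED = ("flank", "perineum")


def preferred_parts(taxon: str) -> tuple[str, ...]:
    return PREFERRED_PARTS.get(taxon, DEFAULT_PREFERRED)


@dataclass
class ContingencyTable:
    """2 x C table: partner absent/present x focal-tick attachment columns."""

    focal_taxon: str
    partner_taxon: str
    site: str
    coding: str  # "preferred2" | "body5"
    counts: np.ndarray  # shape (2, C), rows: partner absent, partner present
    col_labels: tuple[str, ...]
    testable: bool
    flags: tuple[str, ...] = ()

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class FisherResult:
    p: float
    method: str  # "enumeration" | "monte_carlo"
    n_mc: int | None
    table: ContingencyTable | None = None


@dataclass
class CombinedP:
    z: float
    p: float
    k: int
    per_site_p: tuple[float, ...]
    mode: str  # "one_sided" | "two_sided"
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Table construction


def attachment_contingency(
    survey: SurveyTable,
    focal_taxon: str,
    partner_taxon: str,
    site: str,
    coding: str = "preferred2",
) -> ContingencyTable:
    """Cross-classify each attached focal tick by partner co-infestation.

    The counting unit is the individual attached tick of the focal taxon
    (rows lacking an attachment-site record are excluded); its row is the
    presence of the partner taxon on the same steer-month (any attachment
    site, recorded or not).
    """
    if coding not in ("preferred2", "body5"):
        raise ValueError(f"unknown coding {coding!r}")
    df = survey.data
    here = df.loc[df["site"] == site]
    partner = (
        here.loc[here["taxon"] == partner_taxon]
        .groupby(["month_index", "steer"])["count"]
        .sum()
    )
    infested = set(partner[partner > 0].index)

    focal = here.loc[
        (here["taxon"] == focal_taxon)
        & here["attachment_site"].notna()
        & (here["count"] > 0)
    ]
    if coding == "body5":
        cols = BODY_PARTS
        col_of = {p: i for i, p in enumerate(BODY_PARTS)}
    else:
        cols = ("preferred", "not_preferred")
        pref = set(preferred_parts(focal_taxon))
        col_of = {p: (0 if p in pref else 1) for p in BODY_PARTS}

    counts = np.zeros((2, len(cols)), dtype=int)
    for _, row in focal.iterrows():
        r = 1 if (row["month_index"], row["steer"]) in infested else 0
        counts[r, col_of[row["attachment_site"]]] += int(row["count"])

    flags = []
    testable = True
    if (counts.sum(axis=1) == 0).any():
        flags.append("empty_row")
        testable = False
    if (counts.sum(axis=0) > 0).sum() < 2:
        flags.append("fewer_than_two_nonzero_columns")
        testable = False
    return ContingencyTable(
        focal_taxon=focal_taxon,
        partner_taxon=partner_taxon,
        site=site,
        coding=coding,
        counts=counts,
        col_labels=tuple(cols),
        testable=testable,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Fisher's exact test (2 x C)


def _log_table_prob(table: np.ndarray) -> float:
    """log multivariate-hypergeometric probability of an R x C table."""
    table = np.asarray(table)
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(r + 1).sum()
        + gammaln(c + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _enumerate_2xc(row1_total: int, col_totals: np.ndarray):
    """Yield every first-row vector compatible with the fixed margins."""
    C = len(col_totals)
    suffix = np.concatenate([np.cumsum(col_totals[::-1])[::-1][1:], [0]])

    def rec(j: int, remaining: int, prefix: tuple):
        if j == C - 1:
            if 0 <= remaining <= col_totals[j]:
                yield prefix + (remaining,)
            return
        lo = max(0, remaining - suffix[j])
        hi = min(col_totals[j], remaining)
        for a in range(lo, hi + 1):
            yield from rec(j + 1, remaining - a, prefix + (a,))

    yield from rec(0, row1_total, ())


def fisher_exact(
    table: ContingencyTable | np.ndarray,
    max_enumeration: int = 10**7,
    n_mc: int = 10**5,
    seed: int = 0,
) -> FisherResult:
    """Two-sided Fisher exact p for a 2 x C table.

    p sums the probabilities of all margin-compatible tables no more
    probable than the observed one ("probability <= observed" rule; the
    conventional two-sided definition, which for 2 x 2 reduces to the
    hypergeometric sum).  Enumeration is exact while the count of candidate
    tables stays below ``max_enumeration``; beyond that, ``n_mc``
    margin-preserving Monte-Carlo draws (Patefield algorithm, seeded) give
    p = (1 + #{P* <= P_obs}) / (1 + n_mc).
    """
    if isinstance(table, ContingencyTable):
        if not table.testable:
            raise ValueError(
                f"untestable table ({', '.join(table.flags)}): "
                f"{table.focal_taxon} vs {table.partner_taxon} at {table.site}"
            )
        counts = table.counts
        ref = table
    else:
        counts = np.asarray(table, dtype=int)
        ref = None
    if counts.shape[0] != 2:
        raise ValueError("expected a 2 x C table")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    log_obs = _log_table_prob(counts)
    tol = 1e-9 * max(1.0, abs(log_obs))

    size_bound = np.prod(np.minimum(col, row[0]) + 1.0)
    if size_bound <= max_enumeration:
        total = 0.0
        p = 0.0
        for a in _enumerate_2xc(int(row[0]), col):
            t = np.vstack([a, col - np.asarray(a)])
            lp = _log_table_prob(t)
            prob = np.exp(lp)
            total += prob
            if lp <= log_obs + tol:
                p += prob
        # normalization guard: total == 1 up to float error
        p = min(1.0, p / total)
        return FisherResult(p=p, method="enumeration", n_mc=None, table=ref)

    rng = np.random.default_rng(seed)
    sampler = stats.random_table(row, col)
    draws = np.asarray(sampler.rvs(n_mc, method="patefield", random_state=rng))
    # margins are fixed: only the per-cell factorial term varies across draws
    const = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(counts.sum() + 1)
    lps = const - gammaln(draws + 1).sum(axis=(1, 2))
    hits = int((lps <= log_obs + tol).sum())
    p = (1.0 + hits) / (1.0 + n_mc)
    return FisherResult(p=p, method="monte_carlo", n_mc=n_mc, table=ref)


# ---------------------------------------------------------------------------
# Stouffer combination


def stouffer_combine(
    p_values,
    effect_signs=None,
    mode: str = "one_sided",
) -> CombinedP:
    """Combine per-site p-values via the sum of normal deviates / sqrt(k).

    Without signs, each p is treated as one-sided: z_i = Phi^-1(1 - p_i).
    With ``effect_signs`` (e.g. the direction of preferred-site enrichment,
    for two-sided Fisher p-values), z_i = sign_i * Phi^-1(1 - p_i / 2).  The
    combined p is one-sided (P(Z > z)) or two-sided per ``mode``.  Exact 0/1
    inputs are clamped into the open interval and flagged.
    """
    p = np.asarray(list(p_values), dtype=float)
    k = p.size
    if k < 1:
        raise ValueError("need at least one p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    flags = []
    tiny = np.finfo(float).tiny
    if ((p == 0) | (p == 1)).any():
        flags.append("clamped_boundary_p")
        p = np.clip(p, tiny, 1 - 1e-16)
    if effect_signs is not None:
        signs = np.sign(np.asarray(list(effect_signs), dtype=float))
        if signs.size != k:
            raise ValueError("signs not aligned with p-values")
        signs[signs == 0] = 1.0
        z = signs * stats.norm.isf(p / 2.0)
    else:
        z = stats.norm.isf(p)
    Z = float(z.sum() / np.sqrt(k))
    if mode == "one_sided":
        combined = float(stats.norm.sf(Z))
    elif mode == "two_sided":
        combined = float(2.0 * stats.norm.sf(abs(Z)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    combined = min(max(combined, tiny), 1.0 - 1e-16)
    return CombinedP(
        z=Z, p=combined, k=k, per_site_p=tuple(map(float, p)), mode=mode,
        flags=tuple(flags),
    )


def preferred_enrichment_sign(table: ContingencyTable) -> int:
    """Direction of the partner effect on preferred-site attachment.

    +1 when co-infested focal ticks sit on preferred parts more often than
    non-co-infested ones, -1 otherwise.  Only defined for preferred2 tables.
    """
    if table.coding != "preferred2":
        raise ValueError("enrichment sign requires the preferred2 coding")
    counts = table.counts.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = counts[:, 0] / counts.sum(axis=1)
    if np.isnan(share).any():
        return 1
    return 1 if share[1] >= share[0] else -1


def combine_site_tables(
    tables: list[ContingencyTable],
    signed: bool = True,
    mode: str = "two_sided",
    **fisher_kwargs,
) -> tuple[CombinedP, list[FisherResult]]:
    """Fisher-test each testable site table, then Stouffer-combine.

    With ``signed`` (preferred2 coding only) each two-sided Fisher p enters
    at p/2 with the sign of the observed preferred-site enrichment; the
    unsigned fallback treats every p as one-sided evidence.
    """
    usable = [t for t in tables if t.testable]
    if not usable:
        raise ValueError("no testable site tables")
    results = [fisher_exact(t, **fisher_kwargs) for t in usable]
    pvals = [r.p for r in results]
    signs = None
    if signed and all(t.coding == "preferred2" for t in usable):
        signs = [preferred_enrichment_sign(t) for t in usable]
    combined = stouffer_combine(pvals, effect_signs=signs, mode=mode)
    return combined, results
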