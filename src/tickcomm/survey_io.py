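"""Data model, readers/writers and aggregations for cattle-tick survey tables.

The survey design mirrors a twelve-month sentinel-herd protocol: in each of
four climatic areas, two to four sites (herds) are monitored monthly, twelve
sentinel steers per site, and every adult tick collected is recorded with its
taxon and attachment site on the host body (head, legs, flank, perineum or
tail).  Records are kept long-format: one row per
(site, month, steer, taxon, attachment-site) with a count.

Seven taxa are analysed: *Hyalomma spp*, *A. variegatum*, *Rhipicephalus spp*
(excluding the *Boophilus* subgenus) and the four *Boophilus* species
(*R. annulatus*, *R. decoloratus*, *R. microplus*, *R. geigyi*).  Two extra
codes are carried but excluded from every analysis: BOOPHILUS_UNASSIGNED
(*Boophilus* adults not assignable to species) and UNIDENTIFIED.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Vocabulary

#: Seven taxa entering community / GLM analyses, in canonical order.
ANALYSIS_TAXA = (
    "HYALOMMA_SPP",
    "A_VARIEGATUM",
    "RHIPICEPHALUS_SPP",
    "R_ANNULATUS",
    "R_DECOLORATUS",
    "R_MICROPLUS",
    "R_GEIGYI",
)

#: Full taxon vocabulary (analysis taxa + two codes excluded from analyses).
TAXA = ANALYSIS_TAXA + ("BOOPHILUS_UNASSIGNED", "UNIDENTIFIED")

#: Taxa of the Boophilus subgenus (one-host ticks; late-season peaks).
BOOPHILUS_TAXA = ("R_ANNULATUS", "R_DECOLORATUS", "R_MICROPLUS", "R_GEIGYI")

#: Short presence/absence variable codes used in the co-infestation models.
SHORT_CODE = {
    "HYALOMMA_SPP": "H",
    "A_VARIEGATUM": "A",
    "RHIPICEPHALUS_SPP": "R",
    "R_MICROPLUS": "Rm",
    "R_ANNULATUS": "Ra",
    "R_DECOLORATUS": "Rd",
    "R_GEIGYI": "Rg",
}
CODE_TO_TAXON = {v: k for k, v in SHORT_CODE.items()}

#: Host body parts where attached adults are recorded.
BODY_PARTS = ("head", "legs", "flank", "perineum", "tail")

#: Long-format survey CSV columns, in order.
SURVEY_COLUMNS = (
    "area",
    "site",
    "month_index",
    "calendar_month",
    "steer",
    "taxon",
    "attachment_site",
    "count",
)

CLIMATE_COLUMNS = ("area", "month_index", "calendar_month", "rainfall_mm", "temperature_c")


class SurveyValidationError(ValueError):
    """Raised when a survey or climate table violates the data contract."""


# ---------------------------------------------------------------------------
# Containers


@dataclass
class SurveyTable:
    """Long-format tick collection records plus the sampling frame.

    Attributes
    ----------
    data
        One row per (site, month_index, steer, taxon, attachment_site);
        ``attachment_site`` may be missing (NaN), e.g. for explicit
        zero-count rows.  Columns follow :data:`SURVEY_COLUMNS`.
    roster
        site -> ordered tuple of sentinel steer ids.  Twelve steers per
        site under the reference design.
    months
        One row per (area, month_index) giving the calendar month; areas may
        start their survey in different calendar months, so ``month_index``
        is survey-relative (1 = first sampling month of that area).
    """

    data: pd.DataFrame
    roster: dict[str, tuple[str, ...]]
    months: pd.DataFrame

    # -- construction -------------------------------------------------------

    @classmethod
    def from_frame(
        cls,
        data: pd.DataFrame,
        roster: dict[str, tuple[str, ...]] | None = None,
        months: pd.DataFrame | None = None,
        validate: bool = True,
    ) -> "SurveyTable":
        """Build a table from a raw frame, deriving roster/months if absent."""
        data = data.loc[:, list(SURVEY_COLUMNS)].copy()
        data["count"] = data["count"].astype(int)
        data["month_index"] = data["month_index"].astype(int)
        data["calendar_month"] = data["calendar_month"].astype(int)
        if roster is None:
            roster = {
                site: tuple(sorted(grp["steer"].unique()))
                for site, grp in data.groupby("site", sort=True)
            }
        if months is None:
            months = (
                data[["area", "month_index", "calendar_month"]]
                .drop_duplicates()
                .sort_values(["area", "month_index"])
                .reset_index(drop=True)
            )
        table = cls(data=data, roster=dict(roster), months=months)
        if validate:
            table.validate()
        return table

    # -- contract -----------------------------------------------------------

    def validate(self) -> None:
        """Check the data contract; raise SurveyValidationError with offenders."""
        df = self.data
        bad = df.loc[~df["taxon"].isin(TAXA)]
        if len(bad):
            raise SurveyValidationError(
                f"unknown taxon code(s) {sorted(bad['taxon'].unique())} "
                f"in rows {bad.index.tolist()[:10]}"
            )
        has_part = df["attachment_site"].notna()
        bad = df.loc[has_part & ~df["attachment_site"].isin(BODY_PARTS)]
        if len(bad):
            raise SurveyValidationError(
                f"unknown attachment site(s) {sorted(bad['attachment_site'].unique())} "
                f"in rows {bad.index.tolist()[:10]}"
            )
        if (df["count"] < 0).any():
            rows = df.index[df["count"] < 0].tolist()
            raise SurveyValidationError(f"negative counts in rows {rows[:10]}")
        # site -> exactly one area
        multi = df.groupby("site")["area"].nunique()
        if (multi > 1).any():
            raise SurveyValidationError(
                f"site(s) assigned to more than one area: {multi[multi > 1].index.tolist()}"
            )
        key = ["site", "month_index", "steer", "taxon", "attachment_site"]
        dup = df.duplicated(subset=key, keep=False)
        if dup.any():
            raise SurveyValidationError(
                f"duplicate (site, month, steer, taxon, attachment_site) keys "
                f"in rows {df.index[dup].tolist()[:10]}"
            )
        for site, grp in df.groupby("site"):
            known = set(self.roster.get(site, ()))
            stray = set(grp["steer"]) - known
            if stray:
                raise SurveyValidationError(
                    f"steer(s) {sorted(stray)} at site {site} missing from roster"
                )

    # -- convenience --------------------------------------------------------

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(sorted(self.roster))

    @property
    def areas(self) -> tuple[str, ...]:
        return tuple(sorted(self.months["area"].unique()))

    def area_of(self, site: str) -> str:
        areas = self.data.loc[self.data["site"] == site, "area"]
        if len(areas):
            return str(areas.iloc[0])
        raise KeyError(site)

    def site_months(self, site: str) -> tuple[int, ...]:
        """Survey-relative month indices sampled at a site's area."""
        area = self.area_of(site)
        m = self.months.loc[self.months["area"] == area, "month_index"]
        return tuple(sorted(m.astype(int)))

    def total_count(self) -> int:
        return int(self.data["count"].sum())


@dataclass
class AbundanceMatrix:
    """Units x taxa count matrix (unit = site, or site-month sampling event)."""

    frame: pd.DataFrame  # index: unit labels, columns: taxon codes
    unit: str  # "site" or "site_month"
    all_zero_units: tuple[str, ...] = ()

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def row_labels(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def col_labels(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def drop_all_zero(self) -> "AbundanceMatrix":
        keep = self.frame.index.difference(self.all_zero_units, sort=False)
        return AbundanceMatrix(self.frame.loc[keep], self.unit, ())


@dataclass
class CompositionSummary:
    """Collection-level composition: counts and percentage shares.

    Named-taxon shares are expressed over the *identified* total (total minus
    unidentified specimens): that is the denominator under which the shares of
    the three non-Boophilus taxa are conventionally reported.  The
    unidentified share uses the grand total.
    """

    total_collected: int
    taxon_counts: dict[str, int]  # 7 analysis taxa + BOOPHILUS_UNASSIGNED
    unidentified: int

    @property
    def identified(self) -> int:
        return self.total_collected - self.unidentified

    def pct_of_identified(self, taxon: str) -> float:
        return 100.0 * self.taxon_counts.get(taxon, 0) / self.identified

    def pct_of_total(self, taxon: str) -> float:
        return 100.0 * self.taxon_counts.get(taxon, 0) / self.total_collected

    @property
    def pct_unidentified(self) -> float:
        return 100.0 * self.unidentified / self.total_collected

    @property
    def boophilus_total(self) -> int:
        return sum(self.taxon_counts.get(t, 0) for t in BOOPHILUS_TAXA) + self.taxon_counts.get(
            "BOOPHILUS_UNASSIGNED", 0
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for taxon, n in self.taxon_counts.items():
            rows.append(
                {
                    "taxon": taxon,
                    "count": n,
                    "pct_identified": round(self.pct_of_identified(taxon), 2),
                    "pct_total": round(self.pct_of_total(taxon), 2),
                }
            )
        rows.append(
            {
                "taxon": "UNIDENTIFIED",
                "count": self.unidentified,
                "pct_identified": float("nan"),
                "pct_total": round(self.pct_unidentified, 2),
            }
        )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"Total adult ticks collected: {self.total_collected}\n")
        buf.write(
            f"Unidentified: {self.unidentified} "
            f"({self.pct_unidentified:.2f} % of total)\n"
        )
        for taxon, n in sorted(self.taxon_counts.items(), key=lambda kv: -kv[1]):
            buf.write(
                f"{taxon:>22}: {n:>7} ({self.pct_of_identified(taxon):6.2f} % of "
                f"identified, {self.pct_of_total(taxon):6.2f} % of total)\n"
            )
        buf.write(
            f"{'Boophilus subgenus':>22}: {self.boophilus_total:>7} "
            f"({100.0 * self.boophilus_total / self.total_collected:6.2f} % of total)\n"
        )
        return buf.getvalue()


# ---------------------------------------------------------------------------
# Readers / writers  (comma-separated, UTF-8, header required, "" = missing)


def read_survey_table(path) -> SurveyTable:
    """Read a long-format survey CSV and return a validated SurveyTable."""
    df = pd.read_csv(
        path,
        dtype={
            "area": str,
            "site": str,
            "steer": str,
            "taxon": str,
            "attachment_site": str,
        },
        keep_default_na=False,
        na_values=[""],
    )
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise SurveyValidationError(f"survey CSV missing column(s) {sorted(missing)}")
    # area/site/steer must never be missing even with ""-as-NaN parsing
    for col in ("area", "site", "steer", "taxon"):
        if df[col].isna().any():
            rows = df.index[df[col].isna()].tolist()
            raise SurveyValidationError(f"missing {col} in rows {rows[:10]}")
    return SurveyTable.from_frame(df)


def write_survey_table(survey: SurveyTable, path) -> None:
    df = survey.data.loc[:, list(SURVEY_COLUMNS)]
    df.to_csv(path, index=False, na_rep="")


def read_climate_table(path) -> pd.DataFrame:
    """Read a per-area monthly climate CSV (one record per area-month)."""
    df = pd.read_csv(path, dtype={"area": str})
    missing = set(CLIMATE_COLUMNS) - set(df.columns)
    if missing:
        raise SurveyValidationError(f"climate CSV missing column(s) {sorted(missing)}")
    if (df["rainfall_mm"] < 0).any():
        rows = df.index[df["rainfall_mm"] < 0].tolist()
        raise SurveyValidationError(f"negative rainfall in rows {rows[:10]}")
    dup = df.duplicated(subset=["area", "month_index"], keep=False)
    if dup.any():
        raise SurveyValidationError(
            f"duplicate (area, month) climate records in rows {df.index[dup].tolist()[:10]}"
        )
    return df.reset_index(drop=True)


def write_climate_table(climate: pd.DataFrame, path) -> None:
    climate.loc[:, list(CLIMATE_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Aggregations


def aggregate_abundance(
    survey: SurveyTable,
    unit: str = "site",
    taxa: tuple[str, ...] = ANALYSIS_TAXA,
    sites: tuple[str, ...] | None = None,
) -> AbundanceMatrix:
    """Sum counts into a units x taxa matrix.

    ``unit="site"`` pools steers, attachment sites and months; ``"site_month"``
    keeps one row per sampling event.  All-zero units are retained and listed
    in ``all_zero_units``.  UNIDENTIFIED (and, by default, the unassignable
    Boophilus residue) never enter the matrix.
    """
    if not taxa:
        raise ValueError("empty taxon list")
    bad = set(taxa) - set(ANALYSIS_TAXA)
    if bad:
        raise ValueError(f"taxa not eligible for analysis: {sorted(bad)}")
    if unit not in ("site", "site_month"):
        raise ValueError(f"unknown unit {unit!r}")

    df = survey.data
    if sites is not None:
        df = df.loc[df["site"].isin(sites)]
    df = df.loc[df["taxon"].isin(taxa)]

    site_list = tuple(sites) if sites is not None else survey.sites
    if unit == "site":
        grouped = df.groupby(["site", "taxon"])["count"].sum()
        frame = grouped.unstack(fill_value=0).reindex(
            index=list(site_list), columns=list(taxa), fill_value=0
        )
    else:
        labels = [
            f"{site}:m{m:02d}" for site in site_list for m in survey.site_months(site)
        ]
        df = df.assign(
            event=df["site"] + ":m" + df["month_index"].map("{:02d}".format)
        )
        grouped = df.groupby(["event", "taxon"])["count"].sum()
        frame = grouped.unstack(fill_value=0).reindex(
            index=labels, columns=list(taxa), fill_value=0
        )
    frame = frame.fillna(0).astype(int)
    frame.index.name = unit
    zero = tuple(frame.index[frame.sum(axis=1) == 0])
    return AbundanceMatrix(frame=frame, unit=unit, all_zero_units=zero)


def presence_matrix(survey: SurveyTable, sites: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Per steer-month presence/absence indicators for the seven analysis taxa.

    Returns one row per (site, month_index, steer) over the full roster —
    steers with no ticks that month appear with all-zero indicators — with
    columns named by the model variable codes H, A, R, Rm, Ra, Rd, Rg.
    """
    site_list = tuple(sites) if sites is not None else survey.sites
    rows = []
    for site in site_list:
        area = survey.area_of(site)
        cal = dict(
            zip(
                survey.months.loc[survey.months["area"] == area, "month_index"],
                survey.months.loc[survey.months["area"] == area, "calendar_month"],
            )
        )
        for m in survey.site_months(site):
            for steer in survey.roster[site]:
                rows.append((area, site, m, int(cal[m]), steer))
    grid = pd.DataFrame(
        rows, columns=["area", "site", "month_index", "calendar_month", "steer"]
    )
    df = survey.data
    df = df.loc[df["taxon"].isin(ANALYSIS_TAXA)]
    sums = (
        df.groupby(["site", "month_index", "steer", "taxon"])["count"]
        .sum()
        .unstack(fill_value=0)
    )
    sums = sums.reindex(columns=list(ANALYSIS_TAXA), fill_value=0)
    merged = grid.join(
        sums, on=["site", "month_index", "steer"], how="left"
    ).fillna(0)
    for taxon in ANALYSIS_TAXA:
        merged[SHORT_CODE[taxon]] = (merged[taxon] > 0).astype(int)
    return merged.drop(columns=list(ANALYSIS_TAXA))


def summarize_composition(survey: SurveyTable) -> CompositionSummary:
    """Collection totals and percentage shares of each taxon."""
    total = survey.total_count()
    if total == 0:
        raise ValueError("cannot summarize an empty collection")
    by_taxon = survey.data.groupby("taxon")["count"].sum()
    unident = int(by_taxon.get("UNIDENTIFIED", 0))
    counts = {
        t: int(by_taxon.get(t, 0))
        for t in ANALYSIS_TAXA + ("BOOPHILUS_UNASSIGNED",)
    }
    return CompositionSummary(
        total_collected=total, taxon_counts=counts, unidentified=unident
    )


def seasonal_abundance_summary(
    survey: SurveyTable,
    taxon: str,
    site: str,
    factor,
) -> pd.DataFrame:
    """Mean +/- SE adult ticks per steer per month, by seasonal level.

    ``factor`` maps month_index -> level label (a SeasonalFactor or a plain
    mapping).  The mean of a level averages the monthly per-steer means of
    its months; the SE is the standard deviation of those monthly means over
    the months of the level, divided by sqrt(#months) — i.e. the SE reflects
    month-to-month variation, not steer-to-steer variation.  A level sampled
    in a single month has no SE (reported missing).
    """
    mapping = getattr(factor, "levels_by_month", None) or dict(factor)
    n_steers = len(survey.roster[site])
    df = survey.data
    df = df.loc[(df["site"] == site) & (df["taxon"] == taxon)]
    monthly = df.groupby("month_index")["count"].sum()
    rows = []
    for level in sorted(set(mapping.values())):
        months = [m for m, lev in mapping.items() if lev == level]
        means = np.array([monthly.get(m, 0) / n_steers for m in months], dtype=float)
        se = (
            float(np.std(means, ddof=1) / np.sqrt(len(means)))
            if len(means) > 1
            else float("nan")
        )
        rows.append(
            {
                "level": level,
                "mean": float(means.mean()) if len(means) else 0.0,
                "se": se,
                "n_months": len(months),
            }
        )
    return pd.DataFrame(rows)
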