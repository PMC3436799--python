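"""Version-level analytics: release mapping, cohorts, growth, age, timelines.

Swiss-Prot (manually curated) and TrEMBL (automatically annotated) were
released on independent schedules before the UniProt consortium synchronised
them; the packaged release catalogue pairs each early Swiss-Prot version
with the TrEMBL version nearest in release date, so curated and automated
annotation can be compared at matching points in time.

Cohort operations track sets of entries across versions — intersections,
first appearances, entry-age statistics — all keyed on accessions.  Entries
are matched on *any* accession (primary or secondary) so that records merged
between versions are not silently lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .flatfile import AnnotationEntry
from .inference import FixedEffectsResult, PosteriorResult

__all__ = [
    "load_release_catalogue", "map_releases", "intersect_cohort", "new_entries",
    "growth_curve", "average_age", "AgeReport", "timeline",
]


def load_release_catalogue() -> pd.DataFrame:
    """Packaged Swiss-Prot <-> TrEMBL release correspondence (editable TSV)."""
    with resources.files("annozipf.data").joinpath("release_catalogue.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if not df["swissprot_version"].is_monotonic_increasing:
        raise ValueError("catalogue swissprot_version must be strictly increasing")
    return df


def map_releases(catalogue: pd.DataFrame, swissprot_version: int) -> int:
    """TrEMBL version released nearest in time to the given Swiss-Prot version."""
    hit = catalogue.loc[catalogue["swissprot_version"] == swissprot_version, "trembl_version"]
    if hit.empty:
        known = catalogue["swissprot_version"].tolist()
        raise KeyError(f"Swiss-Prot version {swissprot_version} not in catalogue; known: {known}")
    return int(hit.iloc[0])


def _accession_universe(entries: Iterable[AnnotationEntry]) -> set[str]:
    out: set[str] = set()
    for e in entries:
        out.update(e.accessions)
    return out


def intersect_cohort(entries_a: Sequence[AnnotationEntry],
                     entries_b: Sequence[AnnotationEntry]) -> set[str]:
    """Accessions present in both versions (any accession, primary or secondary).

    Matching on the full accession sets tolerates record merges: an entry
    whose old primary accession survives as a secondary accession still
    intersects.  Symmetric and idempotent.
    """
    return _accession_universe(entries_a) & _accession_universe(entries_b)


def new_entries(current: Sequence[AnnotationEntry], prior_union: set[str]) -> set[str]:
    """Accessions of entries appearing for the first time in ``current``.

    ``prior_union`` must aggregate every earlier version's accessions.  An
    entry is new only if none of its accessions has been seen before; the
    returned set holds all accessions of the new entries, so successive
    new-entry sets partition the accession universe.
    """
    out: set[str] = set()
    for e in current:
        if prior_union.isdisjoint(e.accessions):
            out.update(e.accessions)
    return out


def growth_curve(versions: Sequence[tuple[str, Sequence[AnnotationEntry]]]) -> list[int]:
    """Entry counts per version, in version order."""
    if not versions:
        raise ValueError("need at least one version")
    return [len(entries) for _, entries in versions]


def _month_index(d: date) -> int:
    return d.year * 12 + (d.month - 1)


@dataclass
class AgeReport:
    """Mean entry age at a release, at month precision."""

    mean_age_months: float
    mean_creation: date  # nearest month, day fixed to 1
    n_entries: int
    n_unknown_dates: int

    @property
    def age_text(self) -> str:
        months = int(round(self.mean_age_months))
        y, m = divmod(months, 12)
        parts = []
        if y:
            parts.append(f"{y} year" + ("s" if y != 1 else ""))
        if m or not parts:
            parts.append(f"{m} month" + ("s" if m != 1 else ""))
        return " and ".join(parts)

    def to_dict(self) -> dict:
        return {"mean_age_months": self.mean_age_months, "age_text": self.age_text,
                "mean_creation": self.mean_creation.isoformat()[:7],
                "n_entries": self.n_entries, "n_unknown_dates": self.n_unknown_dates}


def average_age(entries: Sequence[AnnotationEntry], release_date: date) -> AgeReport:
    """Mean (release - creation) in months, plus the average creation date.

    Dates are mapped to month indices (year*12 + month); days are ignored.
    Entries with unknown creation dates are excluded and counted.
    """
    known = [e for e in entries if e.creation_date is not None]
    n_unknown = len(entries) - len(known)
    if not known:
        raise ValueError("no entries with known creation dates")
    rel = _month_index(release_date)
    idx = np.array([_month_index(e.creation_date) for e in known], dtype=float)
    mean_idx = float(idx.mean())
    year, month0 = divmod(int(round(mean_idx)), 12)
    return AgeReport(
        mean_age_months=float(rel - mean_idx),
        mean_creation=date(year, month0 + 1, 1),
        n_entries=len(known),
        n_unknown_dates=n_unknown,
    )


def timeline(fit_results, baseline_version: str) -> pd.DataFrame:
    """Per-version alpha deltas from a baseline, with 95% credible bounds.

    ``fit_results`` is either a :class:`FixedEffectsResult` from a joint fit
    (the default route — offsets mu_i are read directly) or a mapping
    version -> :class:`PosteriorResult` of independent fits, in which case
    deltas are computed by differencing draw vectors (mode recorded in the
    ``mode`` column).  Rows: version, delta, delta_lo, delta_hi, alpha_abs.
    """
    rows = []
    if isinstance(fit_results, FixedEffectsResult):
        if fit_results.baseline_label != baseline_version:
            raise ValueError(
                f"joint fit baseline is {fit_results.baseline_label!r}, not {baseline_version!r}")
        base = fit_results.alpha
        rows.append((baseline_version, 0.0, 0.0, 0.0, base.point, "fixed-effects"))
        for label, off in fit_results.offsets.items():
            rows.append((label, off.point, off.ci95[0], off.ci95[1],
                         base.point + off.point, "fixed-effects"))
    else:
        results: Mapping[str, PosteriorResult] = fit_results
        if baseline_version not in results:
            raise ValueError(f"baseline {baseline_version!r} missing from fit results")
        base = results[baseline_version]
        for label, res in results.items():
            if label == baseline_version:
                rows.append((label, 0.0, 0.0, 0.0, base.point, "independent"))
                continue
            m = min(len(res.draws), len(base.draws))
            diff = res.draws[:m] - base.draws[:m]
            lo, hi = np.percentile(diff, [2.5, 97.5])
            rows.append((label, float(diff.mean()), float(lo), float(hi),
                         res.point, "independent"))
    df = pd.DataFrame(rows, columns=["version", "delta", "delta_lo", "delta_hi",
                                     "alpha_abs", "mode"])
    return df
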