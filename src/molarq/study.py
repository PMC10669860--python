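"""Full eruption-quotient study: eligibility, measurement, correlation, reliability.

The analysis mirrors the design of the original study: every radiograph
series is read by two raters, one of whom reads twice (sessions six weeks
apart).  After eligibility filtering and quotient measurement the pipeline
produces

* a correlation table — Spearman rho between quotient and age with 95% CI,
  one cell per tooth (38/48) x sex, computed on a single rater-session
  (default: rater 1, session 2, the second assessment run);
* an intra-rater table — Krippendorff's alpha (interval metric) between
  the two sessions of the dual-session rater, per tooth x sex, with
  cluster-bootstrap CIs;
* an inter-rater table — alpha between rater 1 (configurable session,
  default 2) and rater 2, per tooth x sex.

The two entry points are the model object :class:`EruptionStudy` (built
from records and a :class:`StudyConfig`; ``fit()`` returns a
:class:`StudyResults` with the tables, a ``summary()`` and ``save()``) and
the function :func:`run_full_study` for file-to-file operation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .agreement import (
    RatingsMatrix,
    UndefinedStatisticError,
    alpha_with_ci,
    spearman_rho,
    spearman_with_ci,
)
from .geometry import (
    EligibilityConfig,
    EligibilityResult,
    NonPositiveDistanceError,
    assess_eligibility,
    measure_quotient,
)
from .landmarks import RadiographRecord

__all__ = [
    "StudyConfig",
    "StudyResults",
    "EruptionStudy",
    "run_eligibility",
    "measurement_table",
    "correlation_study",
    "intra_rater_study",
    "inter_rater_study",
    "run_full_study",
    "write_report",
]

_CELLS = [(38, "male"), (48, "male"), (38, "female"), (48, "female")]
_MIN_CORRELATION_N = 5


@dataclass(frozen=True)
class StudyConfig:
    """All analysis switches, stamped into every report for provenance."""

    quotient_direction: str = "m2_over_m3"
    round_lengths: bool = True
    eligibility: EligibilityConfig = field(default_factory=EligibilityConfig)
    alpha_metric: str = "interval"
    ci_level: float = 0.95
    n_boot: int = 2000
    seed: int = 0
    #: (rater, session) whose measurements feed the age correlation
    correlation_session_policy: tuple[str, int] = ("R1", 2)
    #: rater with two sessions, for repeatability
    intra_rater: str = "R1"
    intra_sessions: tuple[int, int] = (1, 2)
    #: (rater, session) pairs compared for reproducibility
    inter_rater_policy: tuple[tuple[str, int], tuple[str, int]] = (("R1", 2), ("R2", 1))

    def as_dict(self) -> dict:
        d = asdict(self)
        d["eligibility"] = asdict(self.eligibility)
        return d


@dataclass
class MeasurementError:
    record_key: tuple
    error: str


def run_eligibility(records: Sequence[RadiographRecord],
                    config: StudyConfig | None = None,
                    ) -> tuple[list[RadiographRecord], dict[str, int],
                               dict[tuple, EligibilityResult]]:
    """Apply the eligibility criteria to every record.

    Returns the included records, a tally of exclusion reasons (a record
    may contribute to several), and the per-record results.  A subject
    excluded on one side may remain on the other; sides are independent.
    """
    config = config or StudyConfig()
    included: list[RadiographRecord] = []
    tally: dict[str, int] = {}
    results: dict[tuple, EligibilityResult] = {}
    for rec in records:
        res = assess_eligibility(rec, config.eligibility)
        results[rec.key] = res
        if res.included:
            included.append(rec)
        else:
            for reason in res.reasons:
                tally[reason.value] = tally.get(reason.value, 0) + 1
    return included, tally, results


def measurement_table(records: Iterable[RadiographRecord],
                      config: StudyConfig | None = None,
                      ) -> tuple[pd.DataFrame, list[MeasurementError]]:
    """Measure the eruption quotient on every record.

    Returns one row per record (subject, side, sex, age, rater, session,
    lengths, quotient) plus the list of records that could not be measured.
    """
    config = config or StudyConfig()
    rows = []
    failures: list[MeasurementError] = []
    for rec in records:
        try:
            meas = measure_quotient(rec, direction=config.quotient_direction,
                                    round_lengths=config.round_lengths)
        except (ValueError, NonPositiveDistanceError) as exc:
            failures.append(MeasurementError(record_key=rec.key, error=str(exc)))
            continue
        rows.append({
            "subject_id": rec.subject_id, "side": rec.side, "sex": rec.sex,
            "age": rec.age, "rater_id": rec.rater_id, "session": rec.session,
            "d_m2": meas.d_m2, "d_m3": meas.d_m3, "quotient": meas.quotient,
            "units": meas.units, "rounded": meas.rounded,
        })
    columns = ["subject_id", "side", "sex", "age", "rater_id", "session",
               "d_m2", "d_m3", "quotient", "units", "rounded"]
    return pd.DataFrame(rows, columns=columns), failures


def _empty_cell(side: int, sex: str, n: int, note: str) -> dict:
    return {"side": side, "sex": sex, "estimate": np.nan, "lcl": np.nan,
            "ucl": np.nan, "n": n, "estimable": False, "note": note}


def correlation_study(measurements: pd.DataFrame,
                      config: StudyConfig | None = None) -> pd.DataFrame:
    """Spearman rho between quotient and age per tooth x sex cell.

    Uses only the rater-session selected by ``correlation_session_policy``.
    Cells with fewer than five measurements are flagged not estimable.
    """
    config = config or StudyConfig()
    rater, session = config.correlation_session_policy
    sel = measurements[(measurements["rater_id"] == rater)
                       & (measurements["session"] == session)]
    rows = []
    for side, sex in _CELLS:
        cell = sel[(sel["side"] == side) & (sel["sex"] == sex)]
        n = len(cell)
        if n < _MIN_CORRELATION_N:
            # too small for the CI; still record the point estimate when
            # rho itself is defined (n >= 3)
            row = _empty_cell(side, sex, n, "n < 5")
            if n >= 3:
                try:
                    row["estimate"] = spearman_rho(
                        cell["quotient"].to_numpy(), cell["age"].to_numpy())
                except UndefinedStatisticError:
                    pass
            rows.append(row)
            continue
        try:
            res = spearman_with_ci(cell["quotient"].to_numpy(),
                                   cell["age"].to_numpy(),
                                   level=config.ci_level)
        except UndefinedStatisticError as exc:
            rows.append(_empty_cell(side, sex, n, str(exc)))
            continue
        rows.append({"side": side, "sex": sex, "estimate": res.rho,
                     "lcl": res.lcl, "ucl": res.ucl, "n": res.n,
                     "estimable": True,
                     "note": "degenerate CI" if res.degenerate else ""})
    return pd.DataFrame(rows)


def _reliability_table(measurements: pd.DataFrame,
                       observers: list[tuple[str, int]],
                       config: StudyConfig, seed_offset: int) -> pd.DataFrame:
    """Alpha per tooth x sex with one (rater, session) column per observer."""
    rows = []
    for i, (side, sex) in enumerate(_CELLS):
        cell = measurements[(measurements["side"] == side)
                            & (measurements["sex"] == sex)]
        cols = {}
        for rater, session in observers:
            sub = cell[(cell["rater_id"] == rater) & (cell["session"] == session)]
            cols[f"{rater}/s{session}"] = sub.set_index("subject_id")["quotient"]
        wide = pd.DataFrame(cols)
        n_units_total = len(wide)
        if n_units_total == 0:
            rows.append(_empty_cell(side, sex, 0, "no units"))
            continue
        matrix = RatingsMatrix.from_frame(wide)
        n_dropped = matrix.n_dropped_units
        try:
            res = alpha_with_ci(matrix, metric=config.alpha_metric,
                                n_boot=config.n_boot, level=config.ci_level,
                                seed=config.seed * 1000 + seed_offset + i)
        except (UndefinedStatisticError, ValueError) as exc:
            rows.append(_empty_cell(side, sex, n_units_total, str(exc)))
            continue
        rows.append({"side": side, "sex": sex, "estimate": res.alpha,
                     "lcl": res.lcl, "ucl": res.ucl, "n": res.n_units,
                     "estimable": True,
                     "note": f"{n_dropped} unit(s) dropped" if n_dropped else ""})
    return pd.DataFrame(rows)


def intra_rater_study(measurements: pd.DataFrame,
                      config: StudyConfig | None = None) -> pd.DataFrame:
    """Repeatability: alpha between the two sessions of the dual-session rater.

    Units are subject-side radiographs of the given tooth and sex; only
    units measurable in both sessions contribute pairs (the rest are
    dropped and counted in the cell note).
    """
    config = config or StudyConfig()
    rater = config.intra_rater
    sessions_present = set(
        measurements.loc[measurements["rater_id"] == rater, "session"])
    if not set(config.intra_sessions) <= sessions_present:
        raise ValueError(
            f"intra-rater study needs rater {rater!r} with sessions "
            f"{config.intra_sessions}; found {sorted(sessions_present)}")
    observers = [(rater, s) for s in config.intra_sessions]
    return _reliability_table(measurements, observers, config, seed_offset=100)


def inter_rater_study(measurements: pd.DataFrame,
                      config: StudyConfig | None = None) -> pd.DataFrame:
    """Reproducibility: alpha between the two raters' selected sessions."""
    config = config or StudyConfig()
    for rater, session in config.inter_rater_policy:
        present = ((measurements["rater_id"] == rater)
                   & (measurements["session"] == session)).any()
        if not present:
            raise ValueError(
                f"inter-rater study needs rater {rater!r} session {session}")
    return _reliability_table(measurements, list(config.inter_rater_policy),
                              config, seed_offset=200)


@dataclass
class StudyResults:
    """Fitted study: the three tables plus exclusion tally and provenance."""

    config: StudyConfig
    n_records: int
    n_included: int
    exclusion_tally: dict[str, int]
    n_measurement_failures: int
    correlation: pd.DataFrame
    intra_rater: pd.DataFrame
    inter_rater: pd.DataFrame
    measurements: pd.DataFrame = field(repr=False, default=None)

    @staticmethod
    def _fmt_table(df: pd.DataFrame, label: str) -> str:
        lines = [label, f"{'Tooth':>5} {'Sex':>8} {'Estimate':>9} "
                        f"{'95% LCL':>9} {'95% UCL':>9} {'n':>6}"]
        for _, r in df.iterrows():
            est = "NE" if pd.isna(r["estimate"]) else f"{r['estimate']:.3f}"
            if r["estimable"]:
                lines.append(f"{r['side']:>5} {r['sex']:>8} {est:>9} "
                             f"{r['lcl']:9.3f} {r['ucl']:9.3f} {int(r['n']):>6}")
            else:
                lines.append(f"{r['side']:>5} {r['sex']:>8} {est:>9} "
                             f"{'NE':>9} {'NE':>9} {int(r['n']):>6}")
        return "\n".join(lines)

    def summary(self) -> str:
        cfg = self.config
        head = [
            "Third molar eruption quotient study",
            "=" * 60,
            f"records: {self.n_records}  included: {self.n_included}  "
            f"measurement failures: {self.n_measurement_failures}",
            f"exclusions: {self.exclusion_tally or 'none'}",
            f"quotient direction: {cfg.quotient_direction}  "
            f"rounded lengths: {cfg.round_lengths}",
            f"alpha metric: {cfg.alpha_metric}  n_boot: {cfg.n_boot}  "
            f"seed: {cfg.seed}",
            f"correlation basis: rater {cfg.correlation_session_policy[0]}, "
            f"session {cfg.correlation_session_policy[1]}",
            "",
            self._fmt_table(self.correlation,
                            "Spearman rho (quotient vs age) by tooth and sex"),
            "",
            self._fmt_table(self.intra_rater,
                            "Intra-rater Krippendorff alpha by tooth and sex"),
            "",
            self._fmt_table(self.inter_rater,
                            "Inter-rater Krippendorff alpha by tooth and sex"),
        ]
        return "\n".join(head)

    def as_dict(self) -> dict:
        def table(df: pd.DataFrame) -> list[dict]:
            out = []
            for _, r in df.iterrows():
                out.append({
                    "tooth": int(r["side"]), "sex": r["sex"],
                    "estimate": None if pd.isna(r["estimate"]) else float(r["estimate"]),
                    "lcl": None if pd.isna(r["lcl"]) else float(r["lcl"]),
                    "ucl": None if pd.isna(r["ucl"]) else float(r["ucl"]),
                    "n": int(r["n"]), "estimable": bool(r["estimable"]),
                    "note": str(r["note"]),
                })
            return out

        return {
            "provenance": {
                "software": f"molarq {_version}",
                "config": self.config.as_dict(),
            },
            "counts": {
                "records": self.n_records,
                "included": self.n_included,
                "measurement_failures": self.n_measurement_failures,
                "exclusions": dict(sorted(self.exclusion_tally.items())),
            },
            "correlation": table(self.correlation),
            "intra_rater": table(self.intra_rater),
            "inter_rater": table(self.inter_rater),
        }

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write the three TSV tables and the full-precision JSON report."""
        return write_report(self, outdir)


def write_report(results: StudyResults, outdir: str | Path) -> dict[str, Path]:
    """Write report files: one TSV per table plus a JSON blob.

    TSV estimates are formatted to three decimal places with a fixed column
    order; cells that could not be estimated are written as ``NE`` rather
    than omitted.  The JSON file carries full-precision values, the
    exclusion tally and the complete configuration, and its bytes are a
    deterministic function of the results.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def write_tsv(df: pd.DataFrame, name: str, estimate_label: str) -> None:
        path = outdir / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write(f"tooth\tsex\t{estimate_label}\tlcl\tucl\tn\n")
            for _, r in df.iterrows():
                est = "NE" if pd.isna(r["estimate"]) else f"{r['estimate']:.3f}"
                if r["estimable"]:
                    fh.write(f"{int(r['side'])}\t{r['sex']}\t{est}"
                             f"\t{r['lcl']:.3f}\t{r['ucl']:.3f}\t{int(r['n'])}\n")
                else:
                    fh.write(f"{int(r['side'])}\t{r['sex']}\t{est}\tNE\tNE"
                             f"\t{int(r['n'])}\n")
        paths[name] = path

    write_tsv(results.correlation, "correlation", "rho")
    write_tsv(results.intra_rater, "intra_rater", "alpha")
    write_tsv(results.inter_rater, "inter_rater", "alpha")

    json_path = outdir / "report.json"
    with open(json_path, "w") as fh:
        json.dump(results.as_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["json"] = json_path
    return paths


class EruptionStudy:
    """Model object: an eruption-quotient study over annotation records.

    Parameters
    ----------
    records : sequence of RadiographRecord
        All annotation events (every subject x side x rater x session).
    config : StudyConfig, optional
        Analysis switches; defaults reproduce the published design.

    ``fit()`` runs eligibility filtering, quotient measurement and the
    three statistical studies, returning a :class:`StudyResults`.
    """

    def __init__(self, records: Sequence[RadiographRecord],
                 config: StudyConfig | None = None):
        self.records = list(records)
        self.config = config or StudyConfig()

    @classmethod
    def from_annotations(cls, path: str | Path,
                         config: StudyConfig | None = None) -> "EruptionStudy":
        from .landmarks import read_annotations
        return cls(read_annotations(path), config=config)

    def fit(self) -> StudyResults:
        cfg = self.config
        included, tally, _ = run_eligibility(self.records, cfg)
        measurements, failures = measurement_table(included, cfg)
        return StudyResults(
            config=cfg,
            n_records=len(self.records),
            n_included=len(included),
            exclusion_tally=tally,
            n_measurement_failures=len(failures),
            correlation=correlation_study(measurements, cfg),
            intra_rater=intra_rater_study(measurements, cfg),
            inter_rater=inter_rater_study(measurements, cfg),
            measurements=measurements,
        )


def run_full_study(annotation_path: str | Path, outdir: str | Path,
                   config: StudyConfig | None = None) -> StudyResults:
    """File-to-file pipeline: read annotations, fit the study, write reports."""
    study = EruptionStudy.from_annotations(annotation_path, config=config)
    results = study.fit()
    results.save(outdir)
    return results
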