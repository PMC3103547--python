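"""Z-score profiles and tolerance/specificity classification of sites.

A site's mutability is read off the distribution of its 19 substitution
effects.  With population mean mu and standard deviation sigma, each
substitution's Z-score is (x - mu)/sigma and the classification threshold
is half the standard deviation (HSTD = sigma/2):

* tolerance    — ``non-tolerable`` iff |mu| > HSTD, else ``tolerable``;
* specificity  — ``specific`` iff more than 20% of substitutions have
  |effect| > HSTD *and* those exceeding effects include both favorable and
  unfavorable directions, else ``non-specific``;
* pKa metric   — ``sensitive`` iff the mean cumulative |pKa shift| exceeds
  2 pK units; ``specific`` iff shifts differ across substitutions by more
  than 2 pK units (max - min).

The classifier applies the stated rules only; a prose-style override (for
sites judged tolerable despite a formally exceeding mean) can be attached
as an annotation but never changes the formal label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ENERGY_METRICS = ("folding", "binding")
METRICS = ENERGY_METRICS + ("pka",)

TOLERABLE, NON_TOLERABLE = "tolerable", "non-tolerable"
SPECIFIC, NON_SPECIFIC = "specific", "non-specific"
SENSITIVE, NON_SENSITIVE = "sensitive", "non-sensitive"

SPECIFICITY_FRACTION = 0.20
PKA_CUTOFF = 2.0  # pK units, cumulative over titratable groups


@dataclass
class SiteProfile:
    site: str
    metric: str
    effects: np.ndarray
    substitutions: list[str] | None = None  # one-letter codes, aligned

    def __post_init__(self):
        self.effects = np.asarray(self.effects, dtype=float)
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.effects.shape != (19,):
            raise ValueError(f"expected 19 effect values, got {self.effects.shape}")
        if not np.all(np.isfinite(self.effects)):
            raise ValueError("effects must be finite")

    @property
    def mean(self) -> float:
        return float(self.effects.mean())

    @property
    def std(self) -> float:
        """Population (divide-by-n) standard deviation."""
        return float(self.effects.std(ddof=0))

    def std_mode(self, mode: str = "population") -> float:
        if mode == "population":
            return self.std
        if mode == "sample":
            return float(self.effects.std(ddof=1))
        raise ValueError(f"unknown std mode {mode!r}")

    @property
    def hstd(self) -> float:
        return self.std / 2.0

    @property
    def zscores(self) -> np.ndarray:
        sigma = self.std
        if sigma == 0.0:
            raise ValueError("degenerate distribution: sigma = 0, Z-scores undefined")
        return (self.effects - self.mean) / sigma


def site_profile(effects, metric: str, site: str = "site",
                 substitutions: list[str] | None = None) -> SiteProfile:
    p = SiteProfile(site=site, metric=metric, effects=effects,
                    substitutions=substitutions)
    if p.std == 0.0:
        raise ValueError("degenerate distribution: sigma = 0")
    return p


def classify_tolerance(p: SiteProfile) -> str:
    """non-tolerable iff |mean| strictly exceeds HSTD (energy metrics)."""
    if p.metric not in ENERGY_METRICS:
        raise ValueError("tolerance applies to energy metrics; use classify_pka")
    return NON_TOLERABLE if abs(p.mean) > p.hstd else TOLERABLE


def classify_specificity(p: SiteProfile) -> str:
    """specific iff >20% of substitutions exceed HSTD in magnitude and the
    exceeding effects go in both directions."""
    if p.metric not in ENERGY_METRICS:
        raise ValueError("specificity applies to energy metrics; use classify_pka")
    exceed = p.effects[np.abs(p.effects) > p.hstd]
    if len(exceed) / 19.0 <= SPECIFICITY_FRACTION:
        return NON_SPECIFIC
    if (exceed > 0).any() and (exceed < 0).any():
        return SPECIFIC
    return NON_SPECIFIC


def classify_pka(sum_shifts) -> tuple[str, str]:
    """(sensitivity, specificity) of a site's 19 cumulative |pKa shifts|."""
    v = np.asarray(sum_shifts, dtype=float)
    if v.shape != (19,):
        raise ValueError(f"expected 19 values, got {v.shape}")
    if np.any(v < 0.0):
        raise ValueError("cumulative |pKa shifts| must be non-negative")
    sensitivity = SENSITIVE if v.mean() > PKA_CUTOFF else NON_SENSITIVE
    specificity = SPECIFIC if (v.max() - v.min()) > PKA_CUTOFF else NON_SPECIFIC
    return sensitivity, specificity


@dataclass
class SiteClassification:
    site: str
    metric: str
    tolerance: str | None = None
    specificity: str | None = None
    pka_sensitivity: str | None = None
    pka_specificity: str | None = None
    rationale: str = ""
    prose_override: str | None = None  # annotation only; never computed

    @property
    def label(self) -> str:
        if self.metric == "pka":
            return f"{self.pka_sensitivity} {self.pka_specificity}"
        return f"{self.tolerance} {self.specificity}"


def classify_profile(p: SiteProfile, prose_override: str | None = None) -> SiteClassification:
    if p.metric == "pka":
        sens, spec = classify_pka(p.effects)
        return SiteClassification(
            site=p.site, metric=p.metric,
            pka_sensitivity=sens, pka_specificity=spec,
            rationale=(
                f"mean cumulative shift {p.mean:.2f} pK vs cutoff {PKA_CUTOFF}; "
                f"spread {p.effects.max() - p.effects.min():.2f} pK"
            ),
            prose_override=prose_override,
        )
    tol = classify_tolerance(p)
    spec = classify_specificity(p)
    n_exceed = int((np.abs(p.effects) > p.hstd).sum())
    return SiteClassification(
        site=p.site, metric=p.metric, tolerance=tol, specificity=spec,
        rationale=(
            f"|mean| {abs(p.mean):.2f} vs HSTD {p.hstd:.2f} kcal/mol; "
            f"{n_exceed}/19 substitutions exceed HSTD"
        ),
        prose_override=prose_override,
    )


# Reading of the ">20%" rule, logged into every report (the alternative
# reading counts direction changes rather than HSTD exceedance).
_SPECIFICITY_RULE_NOTE = (
    "specificity rule: specific iff >20% of substitutions exceed HSTD in "
    "magnitude and exceeding effects include both favorable and unfavorable "
    "directions"
)


def site_report(
    profiles: list[SiteProfile],
    classifications: list[SiteClassification] | None = None,
    overrides: dict[tuple[str, str], str] | None = None,
) -> dict:
    """JSON-serializable report: per-substitution effects, ascending
    Z-scores, formal labels and any prose-override annotations."""
    if not profiles:
        raise ValueError("at least one profile required")
    overrides = overrides or {}
    if classifications is None:
        classifications = [
            classify_profile(p, overrides.get((p.site, p.metric))) for p in profiles
        ]
    by_key = {(c.site, c.metric): c for c in classifications}
    sections = []
    for p in profiles:
        c = by_key[(p.site, p.metric)]
        z = p.zscores
        order = np.argsort(z, kind="stable")
        subs = p.substitutions or [f"sub{i}" for i in range(19)]
        sections.append(
            {
                "site": p.site,
                "metric": p.metric,
                "effects": {subs[i]: float(p.effects[i]) for i in range(19)},
                "zscores_ascending": [
                    {"substitution": subs[int(i)], "z": float(z[int(i)])}
                    for i in order
                ],
                "mean": p.mean,
                "std": p.std,
                "hstd": p.hstd,
                "formal_label": c.label,
                "prose_override": c.prose_override,
                "rationale": c.rationale,
            }
        )
    return {"note": _SPECIFICITY_RULE_NOTE, "sections": sections}


def write_report(report: dict, json_path, tsv_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    if tsv_path is not None:
        rows = []
        for sec in report["sections"]:
            for sub, val in sec["effects"].items():
                rows.append(
                    {
                        "site": sec["site"],
                        "metric": sec["metric"],
                        "aa": sub,
                        "value": val,
                        "formal_label": sec["formal_label"],
                    }
                )
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def read_report(json_path) -> dict:
    with open(json_path) as fh:
        return json.load(fh)


def profiles_from_report(report: dict) -> list[SiteProfile]:
    """Rebuild profiles from a report file (round-trip contract)."""
    out = []
    for sec in report["sections"]:
        subs = list(sec["effects"])
        out.append(
            SiteProfile(
                site=sec["site"],
                metric=sec["metric"],
                effects=[sec["effects"][s] for s in subs],
                substitutions=subs,
            )
        )
    return out


def profiles_from_long_table(df: pd.DataFrame) -> list[SiteProfile]:
    """Profiles from a long-format table with columns site, metric, aa, value."""
    required = {"site", "metric", "aa", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"long table needs columns {sorted(required)}")
    out = []
    for (site, metric), grp in df.groupby(["site", "metric"], sort=True):
        grp = grp.sort_values("aa")
        if len(grp) != 19:
            raise ValueError(
                f"site {site} metric {metric}: expected 19 rows, got {len(grp)}"
            )
        out.append(
            SiteProfile(
                site=str(site), metric=str(metric),
                effects=grp["value"].to_numpy(),
                substitutions=list(grp["aa"]),
            )
        )
    return out
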