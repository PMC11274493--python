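"""Latent-to-radiomics interpretation reports.

For each latent feature retained by the guided model, the report lists its
significantly associated radiomics features (Bonferroni-corrected p below
the screen alpha by default, a raw-p mode is available) with their category,
brain-region location and correlation coefficient, sorted by |r|; a
highlighted sublist collects associations with |r| above a reporting
threshold (default 0.5). This is what makes the retained latent features
interpretable: each can be read as a composite of named handcrafted
features in named regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from radguide.guided_selection import CorrelationScreenResult, GuidedModel
from radguide.io_core import parse_radiomics_column

DEFAULT_HIGHLIGHT_R = 0.5

#: column order of the rendered report
REPORT_COLUMNS = ("DL Feature", "Category", "Radiomics Feature",
                  "Brain Region Location", "r")


@dataclass
class LatentInterpretation:
    latent: str
    associations: pd.DataFrame   # significant rows, |r| descending
    highlighted: pd.DataFrame    # |r| > highlight threshold subset
    n_significant: int
    strongest: dict | None       # row dict of the max-|r| association


@dataclass
class InterpretationReport:
    per_latent: dict[str, LatentInterpretation]
    highlight_r: float
    alpha: float
    use_raw_p: bool = False

    @property
    def latents(self) -> list[str]:
        return list(self.per_latent)

    def frame(self, highlighted_only: bool = False) -> pd.DataFrame:
        parts = []
        for li in self.per_latent.values():
            parts.append(li.highlighted if highlighted_only else li.associations)
        if not parts or all(len(p) == 0 for p in parts):
            return pd.DataFrame(columns=list(REPORT_COLUMNS))
        return pd.concat([p for p in parts if len(p)], ignore_index=True)


def _tidy(rows: pd.DataFrame) -> pd.DataFrame:
    out = []
    for _, row in rows.iterrows():
        region, category, feature = parse_radiomics_column(row["radiomics"])
        out.append({
            "DL Feature": row["latent"],
            "Category": category,
            "Radiomics Feature": feature,
            "Brain Region Location": region,
            "r": float(row["r"]),
        })
    return pd.DataFrame(out, columns=list(REPORT_COLUMNS))


def report_from_pairs(pairs: pd.DataFrame, features: list[str], alpha: float,
                      highlight_r: float = DEFAULT_HIGHLIGHT_R,
                      use_raw_p: bool = False) -> InterpretationReport:
    """Build a report from a tidy pair table (latent, radiomics, r, p_*)."""
    per_latent = {}
    pcol = "p_raw" if use_raw_p else "p_corr"
    for latent in features:
        sub = pairs[pairs["latent"] == latent]
        sig = sub[sub[pcol] < alpha]
        sig = sig.reindex(sig["r"].abs().sort_values(ascending=False).index)
        tidy = _tidy(sig)
        high = tidy[tidy["r"].abs() > highlight_r].reset_index(drop=True)
        strongest = tidy.iloc[0].to_dict() if len(tidy) else None
        per_latent[latent] = LatentInterpretation(
            latent=latent, associations=tidy, highlighted=high,
            n_significant=len(tidy), strongest=strongest,
        )
    return InterpretationReport(per_latent=per_latent, highlight_r=highlight_r,
                                alpha=alpha, use_raw_p=use_raw_p)


def build_report(screen_result: CorrelationScreenResult, guided_model: GuidedModel,
                 highlight_r: float = DEFAULT_HIGHLIGHT_R,
                 use_raw_p: bool = False) -> InterpretationReport:
    """Assemble the association report for the model's retained latents.

    The report is a pure function of the screen's pair table, the retained
    feature set and the thresholds; a latent with no significant association
    still gets an (empty) entry.
    """
    missing = [f for f in guided_model.features
               if f not in screen_result.latent_names]
    if missing:
        raise ValueError(f"model feature(s) absent from pair table: {missing}")
    pairs = screen_result.pair_frame(guided_model.features)
    return report_from_pairs(pairs, guided_model.features, screen_result.alpha,
                             highlight_r=highlight_r, use_raw_p=use_raw_p)


def summarize_by(report: InterpretationReport, axis: str) -> pd.Series:
    """Counts of highlighted associations per category or region, sorted."""
    col = {"category": "Category", "region": "Brain Region Location"}.get(axis)
    if col is None:
        raise ValueError("axis must be 'category' or 'region'")
    df = report.frame(highlighted_only=True)
    if df.empty:
        return pd.Series(dtype="int64")
    return df[col].value_counts().sort_values(ascending=False)


def render(report: InterpretationReport, path: str | Path) -> Path:
    """Write the report as CSV plus a human-readable text table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = report.frame()
    df.to_csv(path, index=False)
    txt = path.with_suffix(".txt")
    lines = []
    for latent, li in report.per_latent.items():
        lines.append(f"{latent}  ({li.n_significant} significant association(s), "
                     f"{len(li.highlighted)} with |r| > {report.highlight_r})")
        for _, row in li.highlighted.iterrows():
            lines.append(f"    {row['Category']:<12} {row['Radiomics Feature']:<40} "
                         f"{row['Brain Region Location']:<22} r={row['r']:+.3f}")
    txt.write_text("\n".join(lines) + "\n")
    return path


def read_report_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
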