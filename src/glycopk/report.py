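"""Human-readable markdown report over a completed run directory.

Renders the clearance table in the wide glycoform × group layout
(mean ± SD with significance stars), the reference-normalized clearance
summary, and the serum-profile comparison. No recomputation: every number
is read from the result tables written by the run.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .model import SchemaError

REQUIRED_TABLES = ["nca_results", "normalized_summary", "comparisons"]

CL_FOOTNOTE = (
    "For SC, CL/F — apparent clearance as a function of bioavailability "
    "following SC administration — was used."
)


def _md_table(df: pd.DataFrame, index: bool = False) -> str:
    """Minimal GitHub-flavored markdown rendering of a frame."""
    frame = df.reset_index() if index else df
    headers = [str(c) for c in frame.columns]
    rows = [[("" if pd.isna(v) else str(v)) for v in row] for row in frame.itertuples(index=False)]
    widths = [max(len(h), *(len(r[j]) for r in rows)) if rows else len(h) for j, h in enumerate(headers)]
    fmt = lambda cells: "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"  # noqa: E731
    lines = [fmt(headers), "| " + " | ".join("-" * w for w in widths) + " |"]
    lines += [fmt(r) for r in rows]
    return "\n".join(lines)


def _load(run_dir: Path, name: str) -> pd.DataFrame:
    path = run_dir / f"{name}.csv"
    if not path.exists():
        raise SchemaError(f"incomplete run directory: missing {path.name}")
    return pd.read_csv(path)


def clearance_wide_table(nca: pd.DataFrame, comparisons: pd.DataFrame) -> pd.DataFrame:
    """Glycoform × group table of mean ± SD clearance with stars."""
    stars = {
        (row["group"], row["glycoform"]): row["stars"]
        for _, row in comparisons.iterrows()
        if isinstance(row.get("stars"), str) and row["stars"]
    }
    groups = list(dict.fromkeys(nca["group"]))
    glycoforms = list(dict.fromkeys(nca["glycoform"]))
    label_by_group = {g: nca.loc[nca["group"] == g, "cl_label"].iloc[0] for g in groups}
    table = {}
    for group in groups:
        column = {}
        sub = nca[nca["group"] == group]
        for glycoform in glycoforms:
            values = sub.loc[sub["glycoform"] == glycoform, "clearance_ml_day_kg"].dropna()
            if len(values):
                cell = f"{values.mean():.2f} ± {values.std(ddof=1):.2f}" if len(values) > 1 else f"{values.iloc[0]:.2f}"
                cell += stars.get((group, glycoform), "")
                column[glycoform] = cell
            else:
                column[glycoform] = ""
        table[f"{group} {label_by_group[group]} (mL/day/kg)"] = column
    return pd.DataFrame(table).reindex(glycoforms).rename_axis("glycoform")


def render_report(run_dir: str | Path) -> str:
    """Render the markdown report for a completed run directory."""
    run_dir = Path(run_dir)
    nca = _load(run_dir, "nca_results")
    summary = _load(run_dir, "normalized_summary")
    comparisons = _load(run_dir, "comparisons")

    lines = ["# Glycoform-resolved PK report", ""]
    lines += ["## Clearance by glycoform and group", ""]
    lines.append(_md_table(clearance_wide_table(nca, comparisons), index=True))
    lines += [
        "",
        f"_{CL_FOOTNOTE}_",
        "_Stars mark FDR-significant paired comparisons against the reference "
        "glycoform: \\*\\*\\*\\* p < 0.0001, \\*\\*\\* p < 0.001, \\*\\* p < 0.01, "
        "\\* below the adjusted threshold._",
        "",
        "## Reference-normalized clearance (per-animal ratios)",
        "",
    ]
    if len(summary):
        display = summary.copy()
        for col in ("mean", "sd", "ci95_low", "ci95_high"):
            display[col] = display[col].map(lambda v: f"{v:.3f}")
        lines.append(_md_table(display))
    else:
        lines.append("_no normalized results_")

    serum_path = run_dir / "serum_comparison.csv"
    lines += ["", "## Serum-profile comparison", ""]
    if serum_path.exists():
        serum = pd.read_csv(serum_path)
        flagged = serum[serum["flag"].fillna("") != ""]
        if len(flagged):
            lines.append(_md_table(flagged))
        else:
            lines.append("_none significant_")
    else:
        lines.append("_not requested_")
    lines.append("")
    return "\n".join(lines)


def write_report(run_dir: str | Path, filename: str = "report.md") -> Path:
    run_dir = Path(run_dir)
    text = render_report(run_dir)
    out = run_dir / filename
    out.write_text(text)
    return out
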