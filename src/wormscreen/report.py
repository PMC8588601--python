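"""Plain-text run summaries across the three screen stages."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)


def _section(title: str, body: str) -> str:
    return f"{title}\n{'-' * len(title)}\n{body}\n"


def _try_csv(path: Path) -> "pd.DataFrame | None":
    try:
        return pd.read_csv(path)
    except Exception as exc:  # malformed input skips the section
        logger.warning("skipping %s: %s", path, exc)
        return None


def build_report(run_dir: "str | Path") -> str:
    """Summarise coiler scores, rankings and RT-QuIC calls found in a
    run directory; sections without inputs are simply omitted."""
    run_dir = Path(run_dir)
    parts: list[str] = ["wormscreen run summary", "======================", ""]
    found = False

    for path in sorted(run_dir.glob("**/*.csv")):
        df = _try_csv(path)
        if df is None:
            continue
        cols = set(df.columns)
        if "coiler_score_pct" in cols:
            found = True
            parts.append(_section(f"Coiler scores ({path.name})", df.to_string(index=False)))
        elif {"rank", "entity", "score"} <= cols:
            found = True
            top = df.head(15)
            parts.append(_section(f"Candidate ranking ({path.name}, top 15)", top.to_string(index=False)))
        elif {"sample", "positive"} <= cols:
            found = True
            n_pos = int(df["positive"].sum())
            body = df.to_string(index=False) + f"\n\n{n_pos}/{len(df)} samples positive"
            parts.append(_section(f"RT-QuIC calls ({path.name})", body))

    for path in sorted(run_dir.glob("**/*.fisher.json")):
        try:
            payload = json.loads(path.read_text())
        except Exception as exc:
            logger.warning("skipping %s: %s", path, exc)
            continue
        found = True
        body = (
            f"groups: {payload['groups']}\n"
            f"table (rows=groups, cols=pos/neg): {payload['table']}\n"
            f"Fisher exact p = {payload['fisher_p']:.4g}\n"
            f"threshold = {payload['threshold_rfu']:.1f} rfu"
        )
        parts.append(_section(f"Group comparison ({path.name})", body))

    for path in sorted(run_dir.glob("**/*.json")):
        if path.name.endswith(("manifest.json", "fisher.json")):
            continue
        try:
            payload = json.loads(path.read_text())
        except Exception as exc:
            logger.warning("skipping %s: %s", path, exc)
            continue
        if {"auc", "average_precision"} <= payload.keys():
            found = True
            body = (
                f"AUC = {payload['auc']:.3f}\n"
                f"average precision = {payload['average_precision']:.3f}\n"
                f"rank-sum p = {payload['ranksum_p']:.4g}\n"
                f"held-out ranks: {payload['holdout_ranks']}"
            )
            parts.append(_section(f"LOO validation ({path.name})", body))

    if not found:
        parts.append("(no stage outputs found)")
    return "\n".join(parts) + "\n"
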