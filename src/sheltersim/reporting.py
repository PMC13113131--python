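"""CSV and pretty-table emission, plus run manifests.

CSV in long format is the canonical, machine-checkable output of every
command; the side-by-side tables (census/flow per tier with track rows and
totals) are a secondary human-readable view.  Each output file is
accompanied by a JSON manifest recording the command, inputs, settings and
seed needed to reproduce it byte-for-byte (timestamps aside).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Any

import pandas as pd

from .monte_carlo import CensusEstimate
from .steady_state import SteadyStateTableau

__all__ = ["RunManifest", "write_manifest", "tableau_report", "estimate_report"]

logger = logging.getLogger("sheltersim")


def _package_version() -> str:
    try:
        return version("sheltersim")
    except PackageNotFoundError:  # pragma: no cover - not installed
        return "unknown"


@dataclass
class RunManifest:
    """Provenance record written alongside every output file."""

    command: str
    scenario: str
    settings: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None
    version: str = field(default_factory=_package_version)
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )


def write_manifest(manifest: RunManifest, out_path: str | Path) -> Path:
    """Write the manifest next to ``out_path`` as ``<out>.manifest.json``."""
    path = Path(str(out_path) + ".manifest.json")
    path.write_text(json.dumps(asdict(manifest), indent=2) + "\n")
    return path


def _grid(df: pd.DataFrame, ndigits: int) -> str:
    """Render a tier x track frame with per-tier columns and total column."""
    wide = df.T.copy()
    wide["Total"] = wide.sum(axis=1)
    wide.loc["Total"] = wide.sum(axis=0)
    return wide.round(ndigits).to_string()


def tableau_report(tableaus: list[SteadyStateTableau], gap: float | None = None) -> str:
    """Human-readable census/flow tables mirroring the steady-state layout."""
    parts = []
    for t in tableaus:
        parts.append(f"In-care census: {t.priority} priority")
        parts.append(_grid(t.census, 2))
        parts.append("")
    for t in tableaus:
        parts.append(f"Flow (adoptions/day): {t.priority} priority")
        parts.append(_grid(t.flow, 3))
        parts.append("")
    if gap is not None:
        parts.append(f"Total census gap (F minus S priority): {gap:.2f}")
    return "\n".join(parts) + "\n"


def estimate_report(estimates: list[CensusEstimate]) -> str:
    """Human-readable mean-census tables for Monte Carlo estimates."""
    parts = []
    for e in estimates:
        mode = "with upgrades" if e.settings.upgrades_enabled else "no upgrades"
        parts.append(f"Mean in-care census ({mode}): {e.priority} priority")
        parts.append(_grid(e.mean, 2))
        parts.append(
            f"total {e.total_mean:.2f} (SE {e.total_se:.3f}, "
            f"n={e.n_samples}, burn-in {e.settings.burn_in_days} days)"
        )
        parts.append("")
    return "\n".join(parts) + "\n"
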