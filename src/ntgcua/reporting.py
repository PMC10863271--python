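"""Publication-style outputs: tornado figure, CSV/JSON tables, run manifest."""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .sensitivity import TornadoRow, tornado_frame

__all__ = ["render_tornado", "RunManifest"]


def render_tornado(
    rows: Sequence[TornadoRow],
    path: str | Path | None = None,
    metric: str = "cost",
):
    """Horizontal tornado bars sorted by spread (descending, stable ties).

    ``metric='cost'`` plots the low/high incremental cost per lever (the
    published figure's quantity); ``metric='icur'`` plots the ICUR range.
    Returns the matplotlib figure; also saves to ``path`` when given.
    """
    if not rows:
        raise ValueError("render_tornado needs at least one tornado row")
    lo_attr, hi_attr, key = {
        "cost": ("delta_cost_low", "delta_cost_high", "cost_spread"),
        "icur": ("icur_low", "icur_high", "spread"),
    }[metric]
    ordered = sorted(
        enumerate(rows), key=lambda ir: (-getattr(ir[1], key), ir[0])
    )
    fig, ax = plt.subplots(figsize=(7, 0.6 * len(rows) + 1.2))
    labels = []
    for y, (_, row) in enumerate(reversed(ordered)):
        lo = getattr(row, lo_attr)
        hi = getattr(row, hi_attr)
        left, width = min(lo, hi), abs(hi - lo)
        ax.barh(y, width or 1e-9, left=left, color="#4878a8", height=0.6)
        labels.append(
            f"{row.parameter} ({row.low_setting:g} vs {row.high_setting:g})"
        )
    ax.set_yticks(range(len(rows)), labels)
    xlabel = "incremental cost ($)" if metric == "cost" else "ICUR ($/QALY)"
    ax.set_xlabel(xlabel)
    ax.set_title("One-way sensitivity (tornado)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def tornado_csv(rows: Sequence[TornadoRow], path: str | Path) -> None:
    tornado_frame(rows).to_csv(path, index=False)


@dataclass
class RunManifest:
    """Record of one CLI run: command, inputs, seed, outputs produced."""

    command: str
    config: str | None
    seed: int | None
    outputs: list[str] = field(default_factory=list)

    def add(self, path: str | Path) -> Path:
        path = Path(path)
        self.outputs.append(str(path))
        return path

    def write(self, path: str | Path) -> None:
        from . import __version__

        missing = [p for p in self.outputs if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest lists missing outputs: {missing}")
        payload = {
            "command": self.command,
            "argv": sys.argv,
            "config": self.config,
            "seed": self.seed,
            "package_version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "outputs": self.outputs,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
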