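"""Run manifests and table artifacts for reproducible pipeline runs."""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

TECHNIQUE_ORDER = ["nominal", "linearization", "sigma_points", "pce1", "pce2"]


@dataclass
class RunManifest:
    """Everything needed to reproduce an emitted artifact.

    Deterministic stages reproduce bit-for-bit from a manifest plus the
    package version; Monte-Carlo stages reproduce exactly given the seed.
    """

    model_id: str
    technique: str
    alpha: float | None = None
    confidence: float | None = None
    family: str | None = None
    rel_std: float | None = None
    n_elements: int | None = None
    t_f: float | None = None
    solver_options: dict = field(default_factory=dict)
    seed: int | None = None
    n_samples: int | None = None
    version: str = __version__
    python: str = field(default_factory=platform.python_version)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def technique_table(columns: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Rows = reported quantities, columns in the canonical technique order."""
    order = [t for t in TECHNIQUE_ORDER if t in columns] + \
        [t for t in columns if t not in TECHNIQUE_ORDER]
    rows = sorted({k for col in columns.values() for k in col})
    return pd.DataFrame({t: [columns[t].get(r, np.nan) for r in rows] for t in order},
                        index=rows)


def write_solution(outdir, tag: str, solution, manifest: RunManifest,
                   propagation=None) -> None:
    """Dump a solve: controls CSV, terminal summary, JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prof = solution.controls
    df = pd.DataFrame(prof.values,
                      columns=[f"u{i+1}" for i in range(prof.values.shape[1])])
    df.insert(0, "t_start", prof.grid[:-1])
    df.insert(1, "t_end", prof.grid[1:])
    df.to_csv(outdir / f"{tag}_controls.csv", index=False)
    summary = {"objective": solution.objective, "t_f": solution.t_f,
               "success": bool(solution.success), "iterations": solution.n_iter}
    if propagation is not None:
        for q, (E, Var) in propagation.quantities.items():
            summary[f"E[{q}]"] = E
            summary[f"sqrtVar[{q}]"] = float(np.sqrt(max(Var, 0.0)))
        summary["n_states"] = propagation.n_states
    Path(outdir / f"{tag}_summary.json").write_text(json.dumps(summary, indent=2))
    manifest.to_json(outdir / f"{tag}_manifest.json")
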