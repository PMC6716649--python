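"""Tabular writers and run manifests."""

from __future__ import annotations

import datetime
import hashlib
import json
import os
from dataclasses import asdict, dataclass
from typing import Sequence

import pandas as pd

from . import __version__
from .cea import CEATable
from .sensitivity import OWSAEntry


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit."""

    command: str
    parameters_sha256: str
    scenario: str | None
    seed: int | None
    n_iterations: int | None
    timestamp: str
    package_version: str

    @classmethod
    def create(cls, command: str, params_path: str, scenario: str | None,
               seed: int | None, n_iterations: int | None) -> "RunManifest":
        with open(params_path, "rb") as fh:
            digest = hashlib.sha256(fh.read()).hexdigest()
        return cls(
            command=command, parameters_sha256=digest, scenario=scenario,
            seed=seed, n_iterations=n_iterations,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
            package_version=__version__,
        )

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


def write_cea_table(table: CEATable, path: str) -> None:
    """CSV mirroring the headline results layout (plus 3-s.f. companions)."""
    table.to_frame().to_csv(path, index=False)


def read_cea_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ceac(ceac_df: pd.DataFrame, path: str) -> None:
    """Long-format CEAC CSV (lambda, strategy, probability)."""
    ceac_df.to_csv(path, index=False)


def write_tornado(entries: Sequence[OWSAEntry], path: str) -> None:
    """Tornado CSV sorted by INMB range descending (filter already applied upstream)."""
    df = pd.DataFrame.from_records([
        {"parameter": e.parameter, "low_value": e.low_value, "high_value": e.high_value,
         "inmb_low": e.inmb_low, "inmb_high": e.inmb_high, "inmb_range": e.inmb_range}
        for e in sorted(entries, key=lambda e: e.inmb_range, reverse=True)
    ])
    df.to_csv(path, index=False)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
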