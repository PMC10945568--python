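"""File-exchange adapter for an external property evaluator.

This package never launches an MD engine itself.  Instead, each candidate
is handed over through a work directory: the adapter writes
``candidate_<n>/params.yaml`` and a GROMACS topology, then waits for the
external pipeline to deposit ``candidate_<n>/results.yaml`` — a mapping of
property name to simulated value (or ``{mape_percent: ...}``).  A missing
or malformed results file within the timeout raises, which the optimizer
records as a failed candidate and survives.
"""

from __future__ import annotations

import time
from pathlib import Path
from typing import Dict

import yaml

from .cost import PropertyResult
from .topology import write_topology
from .watermodel import WaterModelParams

__all__ = ["ExternalEvaluator", "read_results_yaml"]


def read_results_yaml(path) -> Dict[str, PropertyResult]:
    """Parse a property-results YAML into :class:`PropertyResult` objects."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    results: Dict[str, PropertyResult] = {}
    for name, value in data.items():
        if isinstance(value, dict) and "mape_percent" in value:
            results[name] = PropertyResult(name=name, mape_percent=float(value["mape_percent"]))
        else:
            results[name] = PropertyResult(name=name, value=value)
    return results


class ExternalEvaluator:
    """Evaluator contract implementation backed by a work directory."""

    def __init__(self, workdir, timeout: float = 86400.0, poll_interval: float = 5.0):
        self.workdir = Path(workdir)
        self.workdir.mkdir(parents=True, exist_ok=True)
        self.timeout = timeout
        self.poll_interval = poll_interval
        self._counter = 0

    def __call__(self, params: WaterModelParams, warm_start=None) -> Dict[str, PropertyResult]:
        self._counter += 1
        cdir = self.workdir / f"candidate_{self._counter:06d}"
        cdir.mkdir(parents=True, exist_ok=True)
        params.to_yaml(cdir / "params.yaml")
        write_topology(params, cdir / "water.itp")
        if warm_start is not None and isinstance(warm_start, WaterModelParams):
            warm_start.to_yaml(cdir / "warm_start_params.yaml")

        results_path = cdir / "results.yaml"
        deadline = time.monotonic() + self.timeout
        while not results_path.exists():
            if time.monotonic() >= deadline:
                raise TimeoutError(f"no results produced for {cdir.name} within {self.timeout}s")
            time.sleep(self.poll_interval)
        return read_results_yaml(results_path)
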