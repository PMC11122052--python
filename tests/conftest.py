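"""Shared fixtures: a small synthetic scenario and text-fixture builders."""

from __future__ import annotations

import hashlib
from pathlib import Path

import pytest

from mirderep import synthetic_data as sd


SMALL = sd.SyntheticScenario(
    seed=7,
    n_genes=400,
    n_pathways=40,
    pathway_size=(5, 60),
    n_mirnas=6,
    target_set_size=(20, 100),
    n_planted_pairs=2,
    planted_min_pathway_size=40,
    planted_min_targets=60,
    n_planted_aging=6,
    n_planted_reversal=3,
    n_planted_widespread=4,
)


@pytest.fixture(scope="session")
def small_bundle() -> sd.ScenarioBundle:
    """A reduced scenario shared across unit tests (read-only)."""
    return sd.simulate_scenario(SMALL)


@pytest.fixture(scope="session")
def small_inputs(small_bundle, tmp_path_factory) -> dict[str, Path]:
    """The small scenario written to disk once per session."""
    outdir = tmp_path_factory.mktemp("small_inputs")
    return sd.write_scenario(small_bundle, outdir)


def write_text(path: Path, text: str) -> Path:
    path.write_text(text, encoding="utf-8")
    return path


def directory_hash(root: Path) -> str:
    """Order-independent content hash of every file under ``root``."""
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(root)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()
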