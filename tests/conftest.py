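"""Shared fixtures: a session-scoped synthetic run and record builders."""

from __future__ import annotations

import numpy as np
import pytest

from molmatch.config import PipelineConfig, SimConfig
from molmatch.molecules import TrueMolecule
from molmatch.preprocess import ReadRecord


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def reference(sim_config):
    from molmatch.reference import generate_reference
    return generate_reference(sim_config)


@pytest.fixture(scope="session")
def run(tmp_path_factory):
    """One full pipeline run on the standard configuration."""
    from molmatch.pipeline import run_all
    outdir = tmp_path_factory.mktemp("run")
    return run_all(SimConfig(seed=1), PipelineConfig(), outdir)


def make_record(**kw) -> ReadRecord:
    base = dict(
        platform="short", query_name="q0", mapped=True, chrom="chr1",
        start=100, blocks=((100, 191),), strand="+", mapq=255,
        alignment_count=1, raw_barcode="A" * 16, corrected_barcode="A" * 16,
        raw_umi="C" * 12, corrected_umi="C" * 12,
    )
    base.update(kw)
    if base["blocks"]:
        base["start"] = base["blocks"][0][0]
    return ReadRecord(**base)


def long_record_from_molecule(mol: TrueMolecule) -> ReadRecord:
    """In-memory long-read record for a ground-truth molecule (already
    canonicalized, tag attached), bypassing SAM serialization."""
    return ReadRecord(
        platform="long", query_name=f"mol{mol.molecule_id}", mapped=True,
        chrom=mol.chrom, start=mol.blocks[0][0], blocks=tuple(mol.blocks),
        strand=mol.strand, mapq=60, alignment_count=1,
        raw_barcode=mol.cell_barcode, corrected_barcode=mol.cell_barcode,
        raw_umi=mol.umi, corrected_umi=mol.umi, tag_key=mol.tag_key)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
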