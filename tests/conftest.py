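"""Shared fixtures: small and full-scale synthetic panels, run once per
session, plus a motif library file."""

from __future__ import annotations

import pandas as pd
import pytest

from promcap.pipeline import RunConfig, run_pipeline
from promcap.simulate import (
    CaptureConfig,
    PanelSimConfig,
    simulate_all,
    write_panel,
)

MOTIF_TSV = (
    "name\tspecies\tconsensus\n"
    "W-box\tTa\tTGAC\n"
    "TTGATC-motif\tTd\tTTGATC\n"
    "I-box\tOs\tGATAAG\n"
    "DRE\tTa\tRCCGAC\n"
    "TATA\tAt\tTATAWA\n"
)


@pytest.fixture(scope="session")
def motifs_path(tmp_path_factory):
    p = tmp_path_factory.mktemp("motifs") / "motifs.tsv"
    p.write_text(MOTIF_TSV)
    return str(p)


def small_config(seed: int = 7, **kw) -> PanelSimConfig:
    kw.setdefault("capture", CaptureConfig(max_mismatch_fraction=0.04))
    return PanelSimConfig(seed=seed, n_homoeo_groups=6, **kw)


@pytest.fixture(scope="session")
def sim6():
    """Small panel (6 triads) used by unit tests."""
    cfg = small_config()
    ref, panel, edits, truth, capture, probes = simulate_all(cfg)
    return {
        "config": cfg,
        "ref": ref,
        "panel": panel,
        "edits": edits,
        "truth": truth,
        "capture": capture,
        "probes": probes,
    }


@pytest.fixture(scope="session")
def sim30(tmp_path_factory, motifs_path):
    """Full study conditions: 30 triads, divergence 0.08, tau 0.04; written to
    disk and pushed through the whole pipeline once."""
    cfg = PanelSimConfig(
        seed=11, n_homoeo_groups=30, capture=CaptureConfig(max_mismatch_fraction=0.04)
    )
    ref, panel, edits, truth, capture, probes = simulate_all(cfg)
    paneldir = tmp_path_factory.mktemp("panel30")
    write_panel(str(paneldir), ref, panel, truth, capture, force=True)
    outdir = tmp_path_factory.mktemp("out30") / "run"
    rc = RunConfig(
        genome=str(paneldir / "genome.fa"),
        gff3=str(paneldir / "annotation.gff3"),
        targets_tsv=str(paneldir / "targets.tsv"),
        panel_tsv=str(paneldir / "truth" / "panel.tsv"),
        vcf_dir=str(paneldir / "vcf"),
        depth_dir=str(paneldir / "depth"),
        repeats=str(paneldir / "repeats.fa"),
        motifs=motifs_path,
        outdir=str(outdir),
    )
    report = run_pipeline(rc)
    return {
        "config": cfg,
        "ref": ref,
        "panel": panel,
        "edits": edits,
        "truth": truth,
        "capture": capture,
        "probes": probes,
        "paneldir": paneldir,
        "outdir": outdir,
        "report": report,
    }


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
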