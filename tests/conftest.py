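from __future__ import annotations

from pathlib import Path

import pytest

from morbidgenes.build import BuildConfig, run_build
from morbidgenes.fixtures import FixtureSpec, generate_universe
from morbidgenes.harmonizer import load_symbol_table


@pytest.fixture()
def symbol_table(tmp_path: Path):
    """Small hand-built HGNC-style table covering all match tiers.

    AMBIG is an alias of two genes; OLD1 is BRCA-like previous symbol; GHOST
    is withdrawn; ALPHA is both an approved symbol and an alias of GAMMA (so
    approved precedence is observable).
    """
    tsv = "\n".join(
        [
            "hgnc_id\tsymbol\tstatus\tprev_symbols\talias_symbols",
            "HGNC:1\tALPHA\tapproved\tOLD1\tA1|AMBIG",
            "HGNC:2\tBETA\tapproved\t\tB1|AMBIG",
            "HGNC:3\tGAMMA\tapproved\tOLD3\tALPHA",
            "HGNC:4\tGHOST\twithdrawn\t\t",
        ]
    )
    path = tmp_path / "hgnc.tsv"
    path.write_text(tsv + "\n")
    return load_symbol_table(path)


@pytest.fixture(scope="session")
def universe(tmp_path_factory: pytest.TempPathFactory):
    """One generated 120-gene universe plus its built panel, reused across
    read-only tests."""
    out = tmp_path_factory.mktemp("universe")
    spec = FixtureSpec(n_genes=120, seed=42)
    truth = generate_universe(spec, out)
    config = BuildConfig.for_universe(out, "v2024_10")
    panel, log = run_build(config)
    return {"dir": out, "spec": spec, "truth": truth, "config": config, "panel": panel, "log": log}


def panel_key(rows):
    """Comparable projection of panel rows: identity, score, met-source set."""
    return [(r.hgnc_id, r.symbol, r.morbidscore, r.met_sources) for r in rows]
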