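import numpy as np
import pytest
from hypothesis import settings

import wlscore as w

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel():
    return w.load_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """One moderate simulated cohort shared by read-only tests."""
    cfg = w.SimulationConfig(n_cases=300, n_controls=80, seed=11)
    gm, phen, truth = w.simulate_cohort(cfg)
    return gm, phen, truth


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    gm, phen, truth = small_cohort
    outdir = tmp_path_factory.mktemp("cohort")
    return w.write_cohort(gm, phen, truth, outdir)


def write_tsv(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(str(v) for v in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def tiny_annotations(tmp_path):
    """Three-SNV annotation file for handmade genotype fixtures."""
    path = write_tsv(
        tmp_path / "ann.tsv",
        ["rsid", "gene", "risk_allele", "other_allele", "ref_freq", "ref_n"],
        [
            ["rs1", "GENE1", "A", "G", 0.3, 1000],
            ["rs2", "GENE2", "C", "T", 0.5, 1000],
            ["rs3", "GENE3", "G", "A", 0.7, 1000],
        ],
    )
    return w.read_annotations(path)
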