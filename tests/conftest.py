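import pathlib

import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

from protaln.index import build_fm_index
from protaln.metrics import evaluate
from protaln.orf_translate import GeneticCode, OrfPolicy
from protaln.seed_align import AlignParams, SubstitutionMatrix, align_read
from protaln.simulate import (
    SimConfig,
    generate_proteome,
    reverse_translate,
    simulate_reads,
)


@pytest.fixture(scope="session")
def sim_dataset():
    """Small end-to-end dataset: proteome, genome, reads, truth, index."""
    cfg = SimConfig(n_proteins=12, n_read_pairs=80, seed=42)
    proteome, go, obo = generate_proteome(cfg)
    genome = reverse_translate(proteome, seed=cfg.seed, config=cfg)
    reads, truth = simulate_reads(genome, cfg)
    index = build_fm_index(proteome)
    return {
        "config": cfg,
        "proteome": proteome,
        "go": go,
        "obo": obo,
        "genome": genome,
        "reads": reads,
        "truth": truth,
        "index": index,
    }


@pytest.fixture(scope="session")
def aligned_results(sim_dataset):
    code = GeneticCode.standard()
    policy = OrfPolicy()
    params = AlignParams()
    matrix = SubstitutionMatrix.blosum62()
    idx = sim_dataset["index"]
    out = []
    for r in sim_dataset["reads"]:
        out.append(
            (
                align_read(r.name, r.seq1, idx, code, policy, params, matrix),
                align_read(r.name, r.seq2, idx, code, policy, params, matrix),
            )
        )
    return out


@pytest.fixture(scope="session")
def toy_obo_path(tmp_path_factory, sim_dataset):
    p = tmp_path_factory.mktemp("go") / "toy.obo"
    p.write_text(sim_dataset["obo"])
    return p
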