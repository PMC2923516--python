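import pytest

from matchrom.genealogy import SupportThresholds
from matchrom.io import ChromosomeLayout, Manifest, StrainInfo
from matchrom.pipeline import PipelineConfig, run_pipeline


def make_layout(n_genes: int = 5, prefix: str = "g") -> ChromosomeLayout:
    genes = [f"{prefix}{i}" for i in range(n_genes)]
    mid = genes[n_genes // 2]
    return ChromosomeLayout(
        genes=genes, mat_locus_after=mid, centromere_after=genes[-2]
    )


def make_manifest(pair_ids, lineages=None) -> Manifest:
    strains = []
    for i, pair in enumerate(pair_ids):
        lineage = lineages[i] if lineages else str(i + 1)
        for mt in ("A", "a"):
            strains.append(StrainInfo(f"{pair}{mt}", mt, lineage, pair))
    return Manifest(strains)


@pytest.fixture(scope="session")
def thresholds():
    return SupportThresholds(bootstrap_reps=200, rng_seed=0)


@pytest.fixture(scope="session")
def e2e_result(tmp_path_factory):
    """Full pipeline on the default study-like simulation (shared; slow)."""
    out = tmp_path_factory.mktemp("e2e")
    cfg = PipelineConfig(
        out_dir=str(out),
        seed=1,
        thresholds=SupportThresholds(bootstrap_reps=200, rng_seed=1),
    )
    return run_pipeline(cfg)
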