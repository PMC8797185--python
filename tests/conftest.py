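import numpy as np
import pandas as pd
import pytest

from spliceprog.io_core import PsiMatrix
from spliceprog.synthetic import SimulationConfig, simulate_all


def make_psi_matrix(values: dict, meta: dict, quality: dict | None = None) -> PsiMatrix:
    """Build a PsiMatrix from {sample: {event: psi}} and {sample: metadata}.

    NaN values get quality 'N' (uncovered) unless overridden.
    """
    psi = pd.DataFrame(values)
    qual = pd.DataFrame("OK", index=psi.index, columns=psi.columns)
    qual = qual.mask(psi.isna(), "N")
    if quality:
        for s, col in quality.items():
            for e, q in col.items():
                qual.at[e, s] = q
    meta_df = pd.DataFrame(meta).T
    meta_df.index.name = "sample"
    return PsiMatrix(psi, qual, meta_df)


def fly_design(n_rep: int = 1) -> dict:
    meta = {}
    for stage in ("adult", "larval"):
        for sex in ("f", "m"):
            for geno in ("control", "mutant"):
                for r in range(n_rep):
                    meta[f"{stage}_{sex}_{geno}_{r}"] = dict(
                        genotype=geno, sex=sex, stage=stage, dataset="emic_ko"
                    )
    return meta


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A compact synthetic dataset shared across read-only tests."""
    cfg = SimulationConfig(
        seed=11, n_genes=60, n_dependent=12, n_low_branch=2, n_sensitive=8,
        n_highpsi=8, n_lowpsi=8, n_ase=10, n_tissue_enriched=8,
    )
    return simulate_all(cfg, tmp_path_factory.mktemp("sim"))
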