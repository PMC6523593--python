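import numpy as np
import pandas as pd
import pytest

import walnutsnp as w


@pytest.fixture(scope="session")
def founders_small():
    cfg = w.SimConfig(n_founders=27, n_sites=2_000, n_scaffolds=10, seed=7)
    gm, truth = w.simulate_founders(cfg)
    return cfg, gm, truth


@pytest.fixture(scope="session")
def annotated_sites(founders_small):
    _, gm, _ = founders_small
    return w.annotate_sites(gm, seed=8)


@pytest.fixture(scope="session")
def family_sim(founders_small):
    """Five closed families of eight, zero genotyping error."""
    _, founders, _ = founders_small
    plan = w.CrossPlan()
    pairs = [(0, 1), (2, 3), (4, 5), (0, 2), (6, 7)]
    for d, s in pairs:
        plan.add(founders.samples[d], founders.samples[s], 8)
    gm, truth = w.simulate_pedigree(founders, plan, seed=9)
    return gm, truth


def make_matrix(geno, scaffold="scaffold_0000", positions=None, ref="A", alt="C"):
    """GenotypeMatrix from a raw dosage array (helper for hand fixtures)."""
    geno = np.asarray(geno, dtype=np.int8)
    n_samples, n_sites = geno.shape
    positions = positions if positions is not None else np.arange(1, n_sites + 1) * 100
    sites = pd.DataFrame(
        {
            "site_id": [f"s{i}" for i in range(n_sites)],
            "scaffold": scaffold,
            "pos": positions,
            "ref": ref,
            "alt": alt,
        }
    )
    return w.GenotypeMatrix([f"ind{i}" for i in range(n_samples)], sites, geno)
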