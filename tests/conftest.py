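import numpy as np
import pytest

from memprop import (DescriptorConfig, ToyMembraneSpec, compute_descriptors,
                     make_toy_membrane_structure)


@pytest.fixture(scope="session")
def config():
    return DescriptorConfig()


@pytest.fixture(scope="session")
def toy_bundle():
    """One small 2-chain helical bundle with labels (session-wide, read-only)."""
    spec = ToyMembraneSpec(n_chains=2, residues_per_chain=40,
                           tm_span=(11, 30), seed=11)
    return make_toy_membrane_structure(spec)


@pytest.fixture(scope="session")
def toy_descriptors(toy_bundle, config):
    model, _ = toy_bundle
    return compute_descriptors(model, config)


@pytest.fixture(scope="session")
def small_dataset(config):
    """Four small labeled structures with descriptor tables precomputed."""
    out = []
    for seed in (21, 22, 23, 24):
        spec = ToyMembraneSpec(n_chains=2, residues_per_chain=36,
                               tm_span=(9, 28), seed=seed)
        model, labels = make_toy_membrane_structure(spec)
        model.structure_id = f"sm{seed}"
        out.append((compute_descriptors(model, config), labels))
    return out


def random_descriptor_table(n_residues, seed, config, n_chains=1,
                            pairs_per_residue=3):
    """Small synthetic descriptor table with random descriptors (test helper)."""
    from memprop.descriptors import ResidueDescriptorTable

    rng = np.random.default_rng(seed)
    per = n_residues // n_chains
    sizes = [per] * (n_chains - 1) + [n_residues - per * (n_chains - 1)]
    chain_of = np.repeat(np.arange(n_chains), sizes)
    pos = np.concatenate([np.arange(sz) for sz in sizes])
    t = rng.integers(0, config.n_torsion_domains, n_residues)
    t[rng.random(n_residues) < 0.1] = -1  # some undefined torsions
    m = n_residues * pairs_per_residue
    raw_i = rng.integers(0, n_residues, m)
    raw_j = rng.integers(0, n_residues, m)
    lo = np.minimum(raw_i, raw_j)
    hi = np.maximum(raw_i, raw_j)
    # same-chain pairs need local sequence separation >= 2
    keep = (chain_of[lo] != chain_of[hi]) | (np.abs(pos[lo] - pos[hi]) >= 2)
    pi, pj = lo[keep], hi[keep]
    dbin = rng.integers(0, config.n_d_bins, len(pi))
    keys = [(str(c), int(p) + 1, "") for c, p in zip(chain_of, pos)]
    return ResidueDescriptorTable(
        structure_id=f"rand{seed}", keys=keys,
        aa3=["ALA"] * n_residues,
        s=rng.integers(0, 20, n_residues).astype(np.int64),
        t=t.astype(np.int64),
        a=rng.integers(0, config.n_acc_bins, n_residues).astype(np.int64),
        accessibility=rng.uniform(0, 100, n_residues),
        centroids=rng.normal(size=(n_residues, 3)),
        chain_of=chain_of.astype(np.int64), pos=pos.astype(np.int64),
        chain_ids=[str(c) for c in range(n_chains)],
        chain_lengths=np.array(sizes),
        scored=np.ones(n_residues, dtype=bool),
        pair_i=pi.astype(np.int64), pair_j=pj.astype(np.int64),
        pair_d=config.d_min + (dbin + 0.5) * config.d_bin_width,
        pair_dbin=dbin.astype(np.int64), config_hash=config.hash())


def random_labels(table, seed, p_tm=0.5):
    rng = np.random.default_rng(seed)
    return {k: ("TM" if rng.random() < p_tm else "EM") for k in table.keys}
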