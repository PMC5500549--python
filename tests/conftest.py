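import numpy as np
import pytest

from polbind import make_bdna_duplex, make_toy_complex

LADDER_LENGTHS = [50, 100, 200, 300, 400, 500, 600, 700, 800]


@pytest.fixture(scope="session")
def duplex():
    return make_bdna_duplex()


@pytest.fixture(scope="session")
def toy_complex(duplex):
    """Five protein residues at nominal 2/4/6/8/20 Å from the duplex."""
    return make_toy_complex(
        duplex,
        [("LYS", 2.0, "P"), ("ASP", 4.0, "T"), ("SER", 6.0, "P"),
         ("THR", 8.0, "T"), ("ALA", 20.0, "P")],
    )


def brute_force_min_distance(model, chain, resi, target_chains):
    """O(N²) heavy-atom distance oracle, independent of the library path."""
    src = [a for a in model.atoms if a.chain == chain and a.resi == resi and a.is_heavy]
    tgt = [a for a in model.atoms if a.chain in target_chains and a.is_heavy]
    best = np.inf
    for a in src:
        for b in tgt:
            d = sum((x - y) ** 2 for x, y in zip(a.coord, b.coord)) ** 0.5
            best = min(best, d)
    return best


def brute_force_shell(model, cutoff):
    """Brute-force contact shell: set of (chain, resi) for protein residues."""
    dna = set(model.chains("nucleic"))
    out = set()
    for chain in model.chains("protein"):
        for resi, _ in model.residues(chain):
            if brute_force_min_distance(model, chain, resi, dna) <= cutoff:
                out.add((chain, resi))
    return out


def random_rigid_transform(rng):
    """Random rotation matrix (QR-based) and translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, rng.normal(scale=20.0, size=3)
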