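import numpy as np
import pytest

from phageome.calibration import CutoffCurve
from phageome.simulate import make_reference_db
from phageome.wgrr import PairwiseHit, ProteinRepertoire


@pytest.fixture(scope="session")
def ref_db():
    """Planted two-family reference database (10 phages per family)."""
    return make_reference_db(seed=11)


@pytest.fixture(scope="session")
def hit_table(ref_db):
    return ref_db.hit_table()


def toy_curve(attribute, alpha=30.0, beta=0.1, gamma=3.0, database="phage_ref"):
    return CutoffCurve(database=database, attribute=attribute,
                       alpha=alpha, beta=beta, gamma=gamma)


@pytest.fixture()
def curves():
    """Hand-set cutoff curves for all three attributes of the phage db."""
    return {
        ("phage_ref", attr): toy_curve(attr)
        for attr in ("family", "lifestyle", "host_phylum")
    }


def make_repertoire(element_id, n, prefix=None):
    prefix = prefix or element_id
    return ProteinRepertoire(element_id, tuple(f"{prefix}_{i + 1}" for i in range(n)))


def reciprocal_hits(pairs, evalue=1e-30, bitscore=None):
    """Forward and reverse hit lists from (query, subject, identity) triples."""
    fwd, rev = [], []
    for q, s, ident in pairs:
        bs = bitscore if bitscore is not None else 400.0 * ident
        fwd.append(PairwiseHit(q, s, ident, evalue, bs))
        rev.append(PairwiseHit(s, q, ident, evalue, bs))
    return fwd, rev


def random_hit_instance(rng, n_a=None, n_b=None, p_hit=0.6, p_reverse=0.85):
    """A random two-element hit instance for oracle comparisons.

    Returns (rep_a, rep_b, hits_ab, hits_ba).  E-values span the 1e-5
    filter boundary; some reverse hits are missing so strict reciprocity is
    exercised; bitscores are independent of identity so the tie-break chain
    matters.
    """
    n_a = n_a or int(rng.integers(1, 11))
    n_b = n_b or int(rng.integers(1, 11))
    rep_a = make_repertoire("A", n_a)
    rep_b = make_repertoire("B", n_b)
    hits_ab, hits_ba = [], []
    for qa in rep_a.protein_ids:
        for qb in rep_b.protein_ids:
            if rng.uniform() > p_hit:
                continue
            ident = float(rng.uniform(0.05, 1.0))
            evalue = 10.0 ** float(rng.uniform(-30, -3))
            bitscore = float(np.round(rng.uniform(20, 500), 1))
            hits_ab.append(PairwiseHit(qa, qb, ident, evalue, bitscore))
            if rng.uniform() < p_reverse:
                ident_r = float(np.clip(ident + rng.normal(0, 0.02), 0.0, 1.0))
                hits_ba.append(
                    PairwiseHit(qb, qa, ident_r,
                                10.0 ** float(rng.uniform(-30, -3)),
                                float(np.round(rng.uniform(20, 500), 1)))
                )
    return rep_a, rep_b, hits_ab, hits_ba
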