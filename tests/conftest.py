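import numpy as np
import pandas as pd
import pytest

from qltdt.family_data import GenotypeMatrix, build_pedigree
from qltdt.simulate import SimulationConfig, simulate_dataset


@pytest.fixture()
def trio_ped(tmp_path):
    """Minimal valid pedigree: two founders and one offspring."""
    p = tmp_path / "trio.ped"
    p.write_text("F1 C1 P1 M1\nF1 P1 0 0\nF1 M1 0 0\n")
    return p


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small but full synthetic dataset on disk (files + truth)."""
    out = tmp_path_factory.mktemp("smallsim")
    cfg = SimulationConfig(seed=1234, n_families=60, n_variants=8, genetic_effect=0.15)
    paths = simulate_dataset(cfg, str(out))
    return cfg, paths


def make_genotypes(dosage, individuals=None, chrom="1"):
    """Build a GenotypeMatrix directly from a dosage array (rows=individuals)."""
    dosage = np.asarray(dosage, dtype=float)
    n, v = dosage.shape
    if individuals is None:
        individuals = [f"I{i}" for i in range(n)]
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(v)],
        "chromosome": chrom,
        "position": np.arange(1, v + 1) * 100,
        "flipped": False,
    })
    return GenotypeMatrix(list(individuals), variants, dosage)


def make_parent_pedigree(n_families, n_offspring=1):
    """Pedigree with n_families independent father-mother-offspring units."""
    rows = []
    for i in range(n_families):
        fam = f"F{i}"
        rows.append((fam, f"{fam}_P1", "0", "0", "1"))
        rows.append((fam, f"{fam}_P2", "0", "0", "2"))
        for j in range(n_offspring):
            rows.append((fam, f"{fam}_C{j}", f"{fam}_P1", f"{fam}_P2", "0"))
    df = pd.DataFrame(rows, columns=["family_id", "individual_id", "father_id", "mother_id", "sex"])
    return build_pedigree(df)
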