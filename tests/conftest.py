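import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from structfig.structure_io import AtomRecord, Chain, Residue, StructureModel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

_RES_POOL = ["ALA", "GLY", "LYS", "ASP", "SER", "TRP"]
_ATOM_POOL = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")]
_SEG_POOL = ["", "SEG1", "SEG2"]


def random_model(rng: np.random.Generator, model_id: str = "1") -> StructureModel:
    """A small random but PDB-round-trippable model: 1-3 chains, varied
    residue names, occasional altlocs / segIDs / HETATMs, all numeric
    fields quantized to their PDB column precision."""
    model = StructureModel(model_id=model_id)
    serial = 1
    for chain_id in "ABC"[: rng.integers(1, 4)]:
        chain = Chain(chain_id)
        res_seq = int(rng.integers(1, 5))
        for _ in range(rng.integers(3, 9)):
            res_name = _RES_POOL[rng.integers(len(_RES_POOL))]
            res = Residue(res_name, res_seq, "")
            n_atoms = int(rng.integers(1, 4))
            for a in range(n_atoms):
                name, element = _ATOM_POOL[rng.integers(len(_ATOM_POOL))]
                res.atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=name,
                        altloc="A" if rng.random() < 0.1 else "",
                        res_name=res_name,
                        chain_id=chain_id,
                        res_seq=res_seq,
                        i_code="",
                        x=round(float(rng.uniform(-99, 99)), 3),
                        y=round(float(rng.uniform(-99, 99)), 3),
                        z=round(float(rng.uniform(-99, 99)), 3),
                        occupancy=round(float(rng.uniform(0, 1)), 2),
                        b_factor=round(float(rng.uniform(0, 99)), 2),
                        element=element,
                        seg_id=_SEG_POOL[rng.integers(len(_SEG_POOL))],
                        is_hetatm=bool(rng.random() < 0.05),
                    )
                )
                serial += 1
            res_seq += int(rng.integers(1, 3))
            chain.residues.append(res)
        model.chains.append(chain)
    return model


@pytest.fixture
def helix30():
    from structfig.fixtures import ideal_helix

    return ideal_helix(30)


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)
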