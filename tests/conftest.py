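import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from lucihits.plate_model import PlateLayout, ScreenDataset, SCREEN_COLUMNS
from lucihits.synthetic_screen import SyntheticScreenConfig, generate_screen

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """A down-scaled screen: 2 plates x 2 replicates, 40 compounds each."""
    return SyntheticScreenConfig(
        n_library_plates=2, n_replicates=2, compounds_per_plate=40, seed=7
    )


@pytest.fixture(scope="session")
def small_screen(small_config):
    dataset, truth = generate_screen(small_config)
    return dataset, truth


def make_mini_dataset(lib_rlu, tnfa_rlu, renilla=100.0, renilla_overrides=None):
    """Handcrafted one-plate 96-well screen with exact RLU values.

    Parameters
    ----------
    lib_rlu : dict
        ``compound_id -> [rlu per replicate]``; all compounds must have the
        same replicate count.
    tnfa_rlu : list of lists
        ``tnfa_rlu[w][r]`` = RLU of TNFa well ``w`` in replicate ``r``
        (>= 3 wells).
    renilla : float
        Renilla counts for every well (firefly = rlu * renilla).
    renilla_overrides : dict, optional
        ``(compound_id, replicate) -> renilla value`` for specific wells.
    """
    renilla_overrides = renilla_overrides or {}
    n_rep = len(next(iter(lib_rlu.values()))) if lib_rlu else len(tnfa_rlu[0])
    rows = "ABCDEFGH"
    roles = {}
    compounds = {}
    for w in range(len(tnfa_rlu)):
        roles[(rows[w], 1)] = "TNFA"
    roles[("A", 2)] = "DMSO"
    roles[("B", 2)] = "GW4064"
    roles[("C", 2)] = "GW4064_TNFA"
    cids = sorted(lib_rlu)
    for i, cid in enumerate(cids):
        pos = (rows[i % 8], 3 + i // 8)
        roles[pos] = "LIBRARY"
        compounds[pos] = cid
    layout = PlateLayout("Q1", 96, roles, compounds)
    layout.validate()

    control_rlu = {"DMSO": 0.1, "GW4064": 0.1, "GW4064_TNFA": 0.5}
    records = []
    for rep in range(1, n_rep + 1):
        tnfa_i = 0
        for pos in sorted(roles, key=lambda rc: (rc[0], rc[1])):
            role = roles[pos]
            if role == "TNFA":
                rlu = tnfa_rlu[tnfa_i][rep - 1]
                tnfa_i += 1
                cid = ""
            elif role == "LIBRARY":
                cid = compounds[pos]
                rlu = lib_rlu[cid][rep - 1]
            else:
                cid = ""
                rlu = control_rlu[role]
            ren = renilla_overrides.get((cid, rep), renilla)
            records.append(
                {
                    "plate_id": "Q1",
                    "replicate": rep,
                    "row": pos[0],
                    "col": pos[1],
                    "role": role,
                    "compound_id": cid,
                    "concentration_M": 1e-5 if role == "LIBRARY" else np.nan,
                    "firefly": rlu * ren,
                    "renilla": ren,
                }
            )
        # reset TNFa well counter per replicate
    wells = pd.DataFrame(records, columns=SCREEN_COLUMNS)
    ds = ScreenDataset(wells, {"Q1": layout})
    ds.validate()
    return ds
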