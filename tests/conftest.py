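import numpy as np
import pytest

from jdpop import ShiftRecord, ShiftTable, SyntheticSpec, gen_mutant_shifts, gen_reference


def make_table(rows, dataset_id="tbl", **kw):
    """rows: iterable of (residue, restype, atom, shift)."""
    return ShiftTable(
        dataset_id,
        kw.pop("construct_label", dataset_id),
        [ShiftRecord(r, t, a, s) for r, t, a, s in rows],
        **kw,
    )


def amide_table(residues, h, n, dataset_id="tbl"):
    rows = []
    for res, hh, nn in zip(residues, h, n):
        rows.append((res, "XXX", "H", hh))
        rows.append((res, "XXX", "N", nn))
    return make_table(rows, dataset_id=dataset_id)


@pytest.fixture
def small_reference():
    """Deterministic two-state reference with 21 well-separated residues."""
    spec = SyntheticSpec(seed=7, n_residues=21, mutation_site=200)
    return spec, gen_reference(spec)


@pytest.fixture
def noiseless_variant(small_reference):
    spec, ref = small_reference
    from dataclasses import replace

    vspec = replace(spec, p_f_true=0.37, noise_h=0.0, noise_n=0.0)
    return ref, gen_mutant_shifts(ref, vspec), 0.37
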