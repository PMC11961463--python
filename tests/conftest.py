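"""Shared fixtures: small simulated datasets and the planted-quality cohort."""

from __future__ import annotations

import pytest

from glycocurate.simulate import SimulationSpec, simulate


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small two-plate, two-site cohort with files written to disk."""
    spec = SimulationSpec(seed=11, n_plates=2, samples_per_plate=30)
    outdir = tmp_path_factory.mktemp("small_sim")
    return simulate(spec, outdir=outdir)


@pytest.fixture(scope="session")
def planted_spec():
    """200 real samples + 8 negative controls, 2 sites, 20 analyte-charges
    per site, a 10% planted low-quality tail."""
    return SimulationSpec(
        seed=20,
        n_plates=4,
        samples_per_plate=52,
        sample_type_mix=(("sample", 200 / 208), ("negative_control", 8 / 208)),
        sites=("IgGI1", "IgGII1"),
        analytes_per_site=10,
        charges=(2, 3),
        fraction_low_quality_spectra=0.10,
    )


@pytest.fixture(scope="session")
def planted_sim(planted_spec, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("planted_sim")
    return simulate(planted_spec, outdir=outdir)
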