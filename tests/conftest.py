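import pytest

from digepipe.io import GelRecord, StudyDesign
from digepipe.pipeline import RunConfig, run_pipeline
from digepipe.simulate import SimulationConfig, simulate_study


def make_design(patients=("p1",), fractions=("cytosol",)):
    """Reciprocal dye-swap design: two gels per patient per fraction."""
    gels = []
    for fraction in fractions:
        for p in patients:
            for rep, orient in ((1, "high"), (2, "low")):
                other = "low" if orient == "high" else "high"
                gels.append(
                    GelRecord(
                        gel_id=f"{fraction[:2]}-{p}-r{rep}",
                        fraction=fraction,
                        patient_id=p,
                        channels={"std": "standard", "A": orient, "B": other},
                    )
                )
    return StudyDesign(gels=gels)


@pytest.fixture(scope="session")
def sim_default():
    """The default-condition synthetic study (6 patients, 3 fractions)."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """A full pipeline run on the default synthetic study, seed 1."""
    outdir = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(RunConfig(outdir=outdir, seed=1))


@pytest.fixture()
def tiny_design():
    return make_design()
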