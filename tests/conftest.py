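import pytest

from igastro import (
    BufferingParams,
    CurdParams,
    DigestionProtocol,
    FormulaSpec,
    StudyManifest,
    synth_study,
    write_bundle,
)


@pytest.fixture
def protocol() -> DigestionProtocol:
    return DigestionProtocol()


@pytest.fixture
def buffering() -> BufferingParams:
    return BufferingParams()


@pytest.fixture
def zero_curd_formula() -> FormulaSpec:
    """Casein-composition formula with no sieve-retained phase."""
    return FormulaSpec(
        name="casein_if_1",
        protein_frac=0.017,
        fat_frac=0.0394,
        whey_casein_ratio=(20, 80),
        profile="casein_dominant",
    )


@pytest.fixture
def curdy_formula() -> FormulaSpec:
    """Formula with an early, heavy curd phase for both nutrients."""
    return FormulaSpec(
        name="curdy",
        protein_frac=0.017,
        fat_frac=0.040,
        whey_casein_ratio=(20, 80),
        profile="casein_dominant",
        curd_protein=CurdParams(onset_min=15, rate_per_min=0.05, plateau=0.5),
        curd_lipid=CurdParams(onset_min=15, rate_per_min=0.04, plateau=0.3),
    )


@pytest.fixture(scope="session")
def study_bundle():
    return synth_study(n_per_profile=1, seed=1)


@pytest.fixture(scope="session")
def bundle_dir(study_bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    write_bundle(study_bundle, d)
    return d


@pytest.fixture(scope="session")
def bundle_manifest(bundle_dir) -> StudyManifest:
    return StudyManifest.from_dir(bundle_dir)
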