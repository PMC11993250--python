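import pytest

from heartscore import (
    DefectClass,
    generate_embryo_table,
    preset_configs,
    reference_blueprint,
)


@pytest.fixture(scope="session")
def blueprint():
    return reference_blueprint()


@pytest.fixture(scope="session")
def wild_bundle():
    return generate_embryo_table(preset_configs()["wild_type"], seed=11)


@pytest.fixture(scope="session")
def trx_bundle():
    return generate_embryo_table(preset_configs()["trx_like"], seed=11)


@pytest.fixture(scope="session")
def both_classes():
    return tuple(DefectClass)


SMALL_TABLE_CSV = """genotype,embryo_id,row,segment,svp_count,tin_count,anterior_cc_count
wt,e1,left,A2,2,4,12
wt,e1,right,A2,2,4,13
wt,e1,left,A3,2,4,
wt,e1,right,A8,2,2,
wt,e2,left,A5,1,5,
"""


@pytest.fixture()
def small_table_path(tmp_path):
    p = tmp_path / "small.csv"
    p.write_text(SMALL_TABLE_CSV, encoding="utf-8")
    return str(p)
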