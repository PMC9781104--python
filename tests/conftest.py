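import numpy as np
import pytest

import clomipk as ck
from clomipk.physiology import PhysiologySpec


@pytest.fixture(scope="session")
def bundle():
    return ck.generate_default_parameters()


@pytest.fixture(scope="session")
def nm_extended(bundle):
    """Extended-horizon NM control simulation used for mass balance."""
    regimen = ck.build_regimen("control")
    grid = np.linspace(0.0, 2000.0, 401)
    return ck.simulate(
        bundle.reference,
        bundle.network,
        list(regimen.doses),
        grid=grid,
        activity_score=ck.ActivityScore.from_value(2.0),
        ivsf=bundle.ivsf,
        t_end=2000.0,
    )


@pytest.fixture(scope="session")
def nm_report(nm_extended):
    return ck.pathway_fractions(nm_extended)


def make_physiology(
    co=300.0,
    gfr=2.0,
    volumes=None,
    enzyme=None,
    weight=60.0,
):
    """Hand-built physiology for toy models (flows split 0.2/0.1/0.2/0.5)."""
    volumes = volumes or {
        "gut_lumen": 1.0,
        "gut_wall": 1.0,
        "liver": 1.5,
        "kidney": 0.3,
        "rest": 33.0,
        "arterial": 1.9,
        "venous": 3.8,
    }
    flows = {
        "gut_wall": 0.2 * co,
        "liver": 0.1 * co,
        "kidney": 0.2 * co,
        "rest": 0.5 * co,
    }
    return PhysiologySpec(
        volumes=volumes,
        blood_flows=flows,
        cardiac_output=co,
        gfr=gfr,
        enzyme_abundance=enzyme or {},
        weight=weight,
        height=165.0,
        age=30.0,
    )


def make_compound(cid="drug", mw=400.0, fu=1.0, kp=1.0, ka=0.5, fa=1.0,
                  renal=False, fsf=1.0):
    return ck.CompoundSpec(
        id=cid,
        molecular_weight=mw,
        fu=fu,
        kp={o: kp for o in ("gut_wall", "liver", "kidney", "rest")},
        ka=ka,
        fa=fa,
        renal_excretion=renal,
        filtration_scaling=fsf,
    )


@pytest.fixture
def toy_physiology():
    return make_physiology()
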