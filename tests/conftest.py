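import numpy as np
import pytest
from hypothesis import settings

from nerveflux.plate_model import InjectionSchedule, PlateRun, Trace, Well, WellMeta
from nerveflux.synthetic_data import default_config, simulate_plate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule() -> InjectionSchedule:
    return InjectionSchedule()


def plateau_trace(
    b: float,
    o: float,
    f: float,
    r: float,
    schedule: InjectionSchedule = InjectionSchedule(),
    ecar_basal: float = 30.0,
) -> Trace:
    """Idealized step trace sitting exactly at each phase plateau."""
    ocr = np.concatenate(
        [
            np.full(schedule.n_basal, float(b)),
            np.full(schedule.n_post, float(o)),
            np.full(schedule.n_post, float(f)),
            np.full(schedule.n_post, float(r)),
        ]
    )
    ecar = np.full(schedule.n_total, float(ecar_basal))
    return Trace(ocr=ocr, ecar=ecar, schedule=schedule)


def make_run(wells: list[tuple[WellMeta, Trace]], schedule=None) -> PlateRun:
    schedule = schedule or wells[0][1].schedule
    return PlateRun(
        schedule=schedule, wells={m.well_id: Well(m, t) for m, t in wells}
    )


def meta(
    wid: str,
    animal: str = "A1",
    group: str = "ctrl",
    negative: bool = False,
    side: str = "left",
    status: str = "pending",
) -> WellMeta:
    return WellMeta(
        well_id=wid,
        animal_id=animal,
        group=group,
        side=side,
        is_negative_control=negative,
        qc_status=status,
    )


@pytest.fixture(scope="session")
def small_cfg():
    """2 genotypes x 3 animals x (2 frags/side x 2 sides + 1 neg ctrl)."""
    return default_config(seed=7, n_animals_per_group=3, fragments_per_side=2)


@pytest.fixture(scope="session")
def sim_run(small_cfg):
    return simulate_plate(small_cfg)
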