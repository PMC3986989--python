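import pandas as pd
import pytest
from hypothesis import settings

import soilrisk as sr

settings.register_profile("default", derandomize=True, deadline=None,
                          max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def site1_params():
    """Packaged fixtures with the Site 1 backgrounds."""
    return sr.default_parameters("Site1")


@pytest.fixture(scope="session")
def site_backgrounds():
    return {"Site1": sr.default_parameters("Site1")[0],
            "Site2": sr.default_parameters("Site2")[0]}


@pytest.fixture(scope="session")
def synth_table():
    """Default synthetic transect table (2 sites x 3 transects x 7 zones)."""
    return sr.generate_transects(sr.GeneratorConfig(seed=0))


@pytest.fixture()
def flat_table(site_backgrounds):
    """Design table with every concentration exactly at background."""
    rows = []
    for site, bg in site_backgrounds.items():
        for t in ("T1", "T2", "T3"):
            for zone in sr.ZONES:
                rows.append({"site": site, "transect": t, "zone": zone,
                             **{m: bg[m] for m in sr.METALS}})
    return sr.validate_samples(pd.DataFrame(rows))
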