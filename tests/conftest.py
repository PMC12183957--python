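import pytest

from mramsim import AnalogConfig, DeviceParams


@pytest.fixture
def params() -> DeviceParams:
    """Low-contrast devices (10 kΩ:20 kΩ at 50 mV): I_P/I_AP = 2."""
    return DeviceParams()


@pytest.fixture
def analog() -> AnalogConfig:
    return AnalogConfig()
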