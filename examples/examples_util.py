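"""Tiny helpers shared by the example scripts."""

import numpy as np
import pandas as pd

from oxiburden import Trace


def build_demo_trace(spo2, pr=None, neonate_id="demo") -> Trace:
    n = len(spo2)
    df = pd.DataFrame(
        {
            "t": np.arange(n) * 2,
            "spo2": np.asarray(spo2, dtype=float),
            "pr": np.full(n, 150.0) if pr is None else np.asarray(pr, dtype=float),
            "pi": np.full(n, 1.5),
            "siq_low": np.zeros(n, dtype=bool),
            "events": np.full(n, "", dtype=object),
        }
    )
    return Trace(neonate_id=neonate_id, device_id="demo", df=df)
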