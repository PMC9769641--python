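"""Small helpers for building aligned three-method profiles in tests."""

import pandas as pd

from simmg_eval import FunctionalProfile


def three_method_profiles(mg: dict, mt: dict, sim: dict, level: str = "KO"):
    """Aligned MG/MT/simMG profiles from 0/1 presence lists per feature.

    All features appear in all three tables (zero-filled), as after
    merging; sample names are S1..Sn.
    """
    features = sorted(set(mg) | set(mt) | set(sim))
    n = max((len(v) for d in (mg, mt, sim) for v in d.values()), default=0)
    samples = [f"S{i + 1}" for i in range(n)]
    out = {}
    for label, rows in (("MG", mg), ("MT", mt), ("simMG", sim)):
        df = pd.DataFrame(0.0, index=features, columns=samples)
        for f, vals in rows.items():
            df.loc[f] = [float(v) * 3.0 for v in vals]
        out[label] = FunctionalProfile(label, level, df)
    return out
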