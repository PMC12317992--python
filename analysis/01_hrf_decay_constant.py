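"""Fit the network decay constant from the canonical hemodynamic response.

The first-order self-coefficient of the network ODE is fixed, not estimated;
its value comes from how fast the canonical double-gamma HRF returns to
baseline.  Sampling the canonical response at TR = 0.72 s and fitting an
exponential to the falling limb (peak down to 10% of peak) gives the
per-sample decay rate used as the diagonal constraint throughout.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from activecortex.evaluation import canonical_hrf, hrf_decay_rate


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="results", help="output directory")
    args = parser.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    lam = hrf_decay_rate(tr_seconds=0.72)
    t = np.arange(0.0, 32.0, 0.72)
    table = np.column_stack([t, canonical_hrf(t)])
    np.savetxt(out / "canonical_hrf.tsv", table, delimiter="\t", header="t_seconds\thrf", comments="")
    (out / "hrf_decay.json").write_text(json.dumps({"lambda_per_sample": lam}, indent=1))
    print(f"canonical HRF falling-limb decay rate: lambda = {lam:.4f} per sample (TR = 0.72 s)")


if __name__ == "__main__":
    main()
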