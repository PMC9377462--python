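"""Regenerate tests/data/catch22_reference.csv.

Runs the published reference implementation (pycatch22) on the 100
deterministic series defined in tests/reference_series.py and freezes its
values.  pycatch22 is needed only to regenerate the fixture, never to run
the package or its test suite.

Usage: python scripts/make_catch22_reference.py
"""

from __future__ import annotations

import csv
import sys
from pathlib import Path

import pycatch22

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "tests"))

from reference_series import N_SERIES, reference_series  # noqa: E402

sys.path.insert(0, str(ROOT / "src"))
from wearphen.catch22 import FEATURE_NAMES  # noqa: E402


def main() -> None:
    out_path = ROOT / "tests" / "data" / "catch22_reference.csv"
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["series_index", "n", *FEATURE_NAMES])
        for i in range(N_SERIES):
            y = reference_series(i)
            res = pycatch22.catch22_all(y.tolist())
            values = dict(zip(res["names"], res["values"]))
            writer.writerow(
                [i, y.size, *(f"{values[name]:.10e}" for name in FEATURE_NAMES)]
            )
    print(f"wrote {out_path}")


if __name__ == "__main__":
    main()
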