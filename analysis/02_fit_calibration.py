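#!/usr/bin/env python
"""Examine the survey calibration fits against the generating truth.

The car-body shielding factor, asphalt shielding factor and dose conversion
factor are fitted per campaign by through-origin regression on the paired
measurements (stage 'calibrate' of the run produced by 01).  This script
reports each fitted factor next to its generating truth and the relative
error; all three should recover within a few tenths of a percent at the
paired-measurement counting statistics.
"""

import json
from pathlib import Path

from radsurvey.synthetic import default_truth_config

RUN = Path("results/survey_run")


def main() -> None:
    truth = default_truth_config()
    with open(RUN / "calibration.json") as fh:
        calib = json.load(fh)
    print(f"{'campaign':8s} {'factor':12s} {'truth':>8s} {'fitted':>10s} "
          f"{'u':>8s} {'rel err %':>9s}")
    for region_id, region in truth.regions.items():
        fit = calib[region_id]
        rows = [
            ("SF_carbody", region.sf_carbody, fit["sf_carbody"], fit["u_sf_carbody"]),
            ("SF_asphalt", region.sf_asphalt, fit["sf_asphalt"], fit["u_sf_asphalt"]),
            ("DCF", truth.dcf, fit["dcf"], fit["u_dcf"]),
        ]
        for name, true_value, fitted, u in rows:
            rel = 100 * (fitted - true_value) / true_value
            print(f"{region_id:8s} {name:12s} {true_value:8.3f} {fitted:10.4f} "
                  f"{u:8.4f} {rel:9.2f}")


if __name__ == "__main__":
    main()
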