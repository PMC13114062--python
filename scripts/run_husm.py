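"""Optional runner for the public HUSM eyes-closed resting EEG dataset.

This script is NOT part of the test suite or acceptance run: it needs
the externally downloaded FigShare dataset ("EEG_Data_New", 34 MDD
patients + 30 healthy controls, 19-channel 10-20 EDF recordings) and
the optional ``mne`` dependency for EDF reading.  Results on the real
data also depend on upstream operator-dependent artifact cleaning (ICA,
bad-segment rejection), which this pipeline deliberately does not
perform, so numbers here are directional, not a line-by-line
reproduction.

Expected layout: a directory of EDF files whose names contain either
"MDD" or "H" (healthy), eyes-closed condition marked "EC", e.g.::

    husm/MDD S1 EC.edf
    husm/H S1 EC.edf

Usage::

    python scripts/run_husm.py --data-dir husm/ --out husm-results/
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from eegsift.evaluation import run_cv  # noqa: E402
from eegsift.modeling import default_specs  # noqa: E402
from eegsift.pipeline import extract_cohort  # noqa: E402
from eegsift.preprocess import read_recording  # noqa: E402
from eegsift.selection import GAConfig  # noqa: E402

CHANNELS = ["Fp1", "Fz", "Fp2"]


def load_cohort(data_dir: Path):
    recordings = []
    for path in sorted(data_dir.glob("*.edf")):
        name = path.stem.upper()
        if "EC" not in name:
            continue
        label = 1 if "MDD" in name else 0
        rec = read_recording(path, fmt="edf", label=label,
                             subject_id=path.stem)
        # EDF channel labels often carry prefixes like "EEG Fp1-LE"
        mapping = {}
        for ch in rec.channel_names:
            for want in CHANNELS:
                if want.upper() in ch.upper():
                    mapping[want] = ch
        rec = rec.pick_channels([mapping[c] for c in CHANNELS])
        rec.channel_names = list(CHANNELS)
        recordings.append(rec)
    if not recordings:
        raise SystemExit(f"no eyes-closed EDF files found in {data_dir}")
    return recordings


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, required=True)
    parser.add_argument("--out", type=Path, default=Path("husm-results"))
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    recordings = load_cohort(args.data_dir)
    print(f"loaded {len(recordings)} recordings "
          f"({sum(r.label for r in recordings)} patients)")
    features = extract_cohort(recordings, progress=True)
    report = run_cv(features, default_specs(seed=args.seed), k=10,
                    seed=args.seed, selector="rs+ga",
                    ga_config=GAConfig(seed=args.seed))
    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "cv_report.json").write_text(report.to_json())
    print(report.aggregate().pivot(index="model", columns="metric",
                                   values="mean").round(4))
    print(f"mean Jaccard stability: {report.jaccard_mean:.3f}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
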