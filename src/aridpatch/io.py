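"""Plain-text export of simulation outputs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .scheduler import SimOutput

__all__ = ["export_output"]


def export_output(out: SimOutput, directory) -> Path:
    """Write summary.csv, per-snapshot plant tables and water grids, and
    a config echo into ``directory``. Grid files are plain CSV matrices
    named <field>_t<days>.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out.to_dataframe().to_csv(directory / "summary.csv", index=False)
    with open(directory / "config.json", "w") as fh:
        json.dump(out.config.to_dict(), fh, indent=2)
    for t, plants, O, W in out.snapshots:
        tag = f"{t:g}"
        df = plants.copy()
        df.insert(0, "t", t)
        df.to_csv(directory / f"plants_t{tag}.csv", index=False)
        np.savetxt(directory / f"O_t{tag}.csv", O, delimiter=",")
        np.savetxt(directory / f"W_t{tag}.csv", W, delimiter=",")
    return directory
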