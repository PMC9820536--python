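"""Write a recording and its analysis results to the canonical file formats.

Recordings are stored as <stem>.csv (time + one column per channel) with a
<stem>.meta.json sidecar; result tables are tidy <stem>.results.csv plus a
JSON summary.
"""

import tempfile
from pathlib import Path

import emgait as eg

out = Path(tempfile.mkdtemp())
rec = eg.generate_animal(eg.treated_config(seed=3, duration=12.0), 0)

eg.write_recording(rec, out / "rat0")
back = eg.load_recording(out / "rat0")
print(f"wrote + reloaded {back.animal_id}: {back.n_samples} samples x "
      f"{len(back.channels)} channels, identical = "
      f"{abs(back.signal - rec.signal).max() < 1e-9 * abs(rec.signal).max()}")

analysis = eg.analyze_recording(back)
eg.write_results(analysis.coordination, out / "rat0_coordination")
print("result files:", sorted(p.name for p in out.iterdir()))
print((out / "rat0_coordination.results.csv").read_text().splitlines()[0])
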