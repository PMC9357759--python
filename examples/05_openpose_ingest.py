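"""Parse OpenPose keypoint JSON into a fixed-shape model input.

Writes a tiny synthetic OpenPose-style directory (three frames, two
candidate detections in one of them), then runs the ingestion pipeline:
parse -> keep the 2 highest-confidence persons -> resample to 25 frames
-> center coordinates.
"""

import json
import tempfile
from pathlib import Path

import numpy as np

from msstgcn import build_layout, read_openpose_json, select_top_persons
from msstgcn.training_eval import prepare_sequences

layout = build_layout("coco18")
rng = np.random.default_rng(0)

workdir = Path(tempfile.mkdtemp())
for i in range(3):
    people = []
    for conf in ([0.9, 0.4] if i == 1 else [0.8]):  # frame 1 has two candidates
        kp = []
        for v in range(18):
            kp += [float(rng.uniform(0, 640)), float(rng.uniform(0, 480)), conf]
        people.append({"pose_keypoints_2d": kp})
    (workdir / f"frame_{i:06d}_keypoints.json").write_text(
        json.dumps({"version": 1.3, "people": people})
    )

frames = read_openpose_json(workdir, layout)
print(f"parsed {len(frames)} frames; candidates per frame: {[len(f) for f in frames]}")

seq = select_top_persons(frames, 2, num_joints=layout.num_joints)
print(f"after top-2 selection: (C,T,V,M) = {seq.data.shape}")
print(f"frame 1, person slot 0 mean confidence: "
      f"{seq.data[2, 1, :, 0].mean():.2f} (the 0.9 candidate won the slot)")

x, y, channels = prepare_sequences([seq], layout)
print(f"model-ready tensor: {x.shape}  channels {channels}")
print("(3 frames were loop-padded up to the 25-frame model input length)")
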