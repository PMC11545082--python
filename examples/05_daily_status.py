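"""Flag birds that lie for most of the photographed day.

The inspection rig photographs each cage repeatedly through the day;
under uniform sampling the fraction of lying observations estimates the
fraction of photographed time spent lying. A bird at or above 50% is
flagged abnormal (possible atrophy) for follow-up by the staff.
"""

from cagepose import daily_status

day = [
    ("cage-03", [1, 1, 1, 0, 1, 1, 0, 1, 0, 1]),  # 7/10 observations lying
    ("cage-04", [0, 0, 1, 0, 0, 0, 1, 0, 0, 0]),  # 2/10
    ("cage-05", [1, 0, 1, 0, 1, 0, 1, 0, 1, 0]),  # exactly half
]

for bird_id, lying_flags in day:
    obs = [(f"09:{i:02d}", bool(v)) for i, v in enumerate(lying_flags)]
    report = daily_status(obs, bird_id=bird_id)
    print(f"{report.bird_id}: lying fraction {report.lying_fraction:.1f} "
          f"-> {report.status}")
# The 50% boundary counts as abnormal: prolonged lying is the early
# warning this pipeline exists to raise.
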