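"""Equalizing sampling effort by replicated day-subsampling.

A patch sampled on more days records more visits purely through effort.
Standardization draws the minimum day count (without replacement, B
replicates) from every better-sampled patch and averages.
"""

import datetime as dt

from bombnet import SamplingCalendar, VisitRecord, min_sampling_days, rarefy_scalars

visits = []
# P1 sampled 4 days with growing activity; P2 sampled only 2 days
for i, total in enumerate([2, 4, 6, 8]):
    visits.append(VisitRecord("P1", dt.date(2007, 6, i + 1), "B. pascuorum",
                              "Trifolium", total))
for i in range(2):
    visits.append(VisitRecord("P2", dt.date(2007, 6, i + 1), "B. pascuorum",
                              "Trifolium", 1))

calendar = SamplingCalendar.from_records(visits)
n_min = min_sampling_days(calendar)
print(f"minimum sampling effort: {n_min} days")

for s in rarefy_scalars(visits, calendar, B=1000, seed=1, per_month=False):
    print(f"patch {s.patch_id}: raw days = {s.n_days}, standardized abundance = "
          f"{s.abundance:.2f}, richness = {s.richness:.2f}")

print()
print("P1's 20 raw visits shrink to ~10: the expected total had it been")
print("sampled on only 2 of its 4 days (the exact expectation is 10).")
print("P2 is already at minimum effort, so its values are exact, not resampled.")
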