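"""Derive adherence endpoints from raw dispensing and MEMS records.

Shows the three endpoint rules on small constructed inputs: the pill-count
percentage, the MEMS +/-6 h on-schedule rule (expected dosing time from a
fitted line), and the intention-to-treat imputation for a withdrawal.
"""

from datetime import date, datetime, timedelta

import pandas as pd

from gspilot import (DispensingRecord, MemsEventLog, itt_impute,
                     mems_on_schedule_pct, pill_count_pct)

# Pill count: 28 pills dispensed, 7 returned after 28 days -> 75% adherence.
rec = DispensingRecord("P001", 28, 7, date(2018, 1, 8), date(2018, 2, 5))
print(f"pill count: {pill_count_pct(rec):.0f}%")

# MEMS: doses at 08:00 every day for a week, then none in week two.  The
# fitted dosing trend is flat at 08:00; only 7 of 14 scheduled days have an
# opening within 6 h of it.
t0 = datetime(2018, 1, 8)
events = [t0 + timedelta(days=d, hours=8) for d in range(7)]
log = MemsEventLog("P001", events, t0, t0 + timedelta(days=14))
print(f"MEMS on-schedule: {mems_on_schedule_pct(log):.0f}%")

# ITT rule: a participant observed at week 2 who withdraws at week 3 is
# scored 0% adherent at weeks 4 and 8 (imputed records created).
records = pd.DataFrame([{"participant_id": "P001", "arm": "mph",
                         "visit_week": 2, "pill_count_pct": 92.9,
                         "mems_pct": 85.7, "imputed": False}])
print(itt_impute(records, withdrawal_week=3).to_string(index=False))
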