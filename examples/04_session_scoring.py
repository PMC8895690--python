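"""One learning session, scored on the five clinical-thinking indicators.

Simulates a competent student on the inguinal-hernia fixture case, then a
student who also submits a classic wrong diagnosis, and prints the radar
indicators plus the teacher's error-diagnosis record.
"""

from vcase.evaluation import build_report
from vcase.fixtures import make_case_fixture, simulate_student
from vcase.session import (
    SessionScene,
    finish,
    start_session,
    submit_diagnosis,
    switch_scene,
)

fx = make_case_fixture("inguinal_hernia", seed=3)

_trace, session = simulate_student(fx, competence=1.0, seed=1, time_noise_sd=0.0)
report = build_report(session)
print("perfect student, nominal completion time:")
for name, value in zip(
    ("rigor", "logic", "systematic", "agility", "expansion"), report.radar
):
    print(f"  {name:>10}: {value:6.2f}")
print(f"  {'total':>10}: {report.total:6.2f}")
print("-> agility caps at 80 when actual time equals recommended time")

s = start_session(fx.playable, "student-b", fx.pipeline)
switch_scene(s, SessionScene.DIAGNOSIS)
submit_diagnosis(s, "Right inguinal hernia")
submit_diagnosis(s, "Lipoma in the groin area")  # classic confusion
finish(s)
rep = build_report(s)
[err] = rep.error_diagnoses
print(f"\nerror record for {err.disease} ({err.discipline}):")
print(f"  correct selected: {err.correct_selected}")
print(f"  error selected:   {err.error_selected}")
print("-> wrong diagnoses are recorded for targeted teaching feedback")
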