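SYNTHETIC VIGNETTE — illustrative stand-in for the study's French factsheets,
which are not redistributed with this package. Content written for this
package; not the text shown to interviewees.

Scenario 4: chemo-radiotherapy (CRT) after surgery.

Imagine that after trans-oral surgery for an oropharyngeal carcinoma your
specialist recommends adjuvant chemo-radiotherapy. Radiotherapy is delivered
in short daily sessions on weekdays for about six weeks, with intravenous
chemotherapy added on a few occasions during that period. Common temporary
side effects include throat irritation, swallowing difficulty (sometimes
requiring a feeding tube), skin inflammation of the neck, nausea, fatigue,
tingling of the limbs, hearing loss, and a drop in white blood cells that can
require hospital admission. Possible long-term effects include persistent
swallowing difficulty, dry mouth, and hardening of the neck skin; a minority
of patients need a gastrostomy tube. Most people return to their previous
life within about three months of finishing treatment.
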