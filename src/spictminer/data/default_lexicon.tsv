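# Default English SPICT-LIS lexicon bundled with spictminer.
# columns: surface	match_kind	script	indicator_id	profiles	comment
# Profiles are nested: every strict entry is also relaxed. Entries marked
# "artifact-seeded" are worded from the SPICT-LIS general-indicator
# definitions rather than an explicit published keyword list, and are meant
# to be replaced by a site-specific dictionary.
#! cue	no	pre	3
#! cue	not	pre	3
#! cue	denies	pre	3
#! cue	denied	pre	3
#! cue	without	pre	3
#! cue	negative for	pre	3
#! scope_breaker	.
#! scope_breaker	;
#! scope_breaker	but
# --- indicator 1: performance status poor or deteriorating ---
poor performance status	literal	segmented	1	relaxed,strict
deteriorating performance status	literal	segmented	1	relaxed,strict
performance status declining	literal	segmented	1	relaxed	artifact-seeded
bedridden	literal	segmented	1	relaxed	artifact-seeded
bedbound	literal	segmented	1	relaxed	artifact-seeded
functional decline	literal	segmented	1	relaxed	artifact-seeded
# --- indicator 2: depends on others for care ---
depends on others for care	literal	segmented	2	relaxed,strict
fully dependent for care	literal	segmented	2	relaxed,strict	artifact-seeded
dependent on caregiver	literal	segmented	2	relaxed	artifact-seeded
needs assistance with daily activities	literal	segmented	2	relaxed	artifact-seeded
# --- indicator 3: carer requires more help and support ---
carer requires more help	literal	segmented	3	relaxed,strict
caregiver requires more support	literal	segmented	3	relaxed,strict	artifact-seeded
caregiver burden	literal	segmented	3	relaxed	artifact-seeded
family exhausted by caregiving	literal	segmented	3	relaxed	artifact-seeded
# --- indicator 4: significant weight loss / remains underweight ---
significant weight loss	literal	segmented	4	relaxed,strict
weight loss	literal	segmented	4	relaxed
underweight	literal	segmented	4	relaxed
hyposthenic build	literal	segmented	4	relaxed
thinner	literal	segmented	4	relaxed
# --- indicator 5: persistent symptoms despite best available treatment ---
persistent symptoms	literal	segmented	5	relaxed,strict
refractory pain	literal	segmented	5	relaxed,strict	artifact-seeded
intractable pain	literal	segmented	5	relaxed,strict	artifact-seeded
pain	literal	segmented	5	relaxed
dyspnea	literal	segmented	5	relaxed
edema	literal	segmented	5	relaxed
delirium	literal	segmented	5	relaxed
xerostomia	literal	segmented	5	relaxed
ascites	literal	segmented	5	relaxed
dysphagia	literal	segmented	5	relaxed
anorexia	literal	segmented	5	relaxed
# --- indicator 6: patient or family asks for palliative care ---
asks for palliative care	literal	segmented	6	relaxed,strict
requests palliative care	literal	segmented	6	relaxed,strict
wishes to focus on quality of life	literal	segmented	6	relaxed,strict	artifact-seeded
palliative care	literal	segmented	6	relaxed
comfort care	literal	segmented	6	relaxed	artifact-seeded
refuses further treatment	literal	segmented	6	relaxed	artifact-seeded
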