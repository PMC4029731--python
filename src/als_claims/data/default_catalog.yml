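# Default ALS claims-phenotyping rule set.
#
# symptom_definitions: the onset rule table. A single high-likelihood code,
# or two distinct moderate-likelihood diagnoses coded in one quarter, marks
# the first-symptom quarter; the category drives bulbar/limb onset calls.
#
# analysis_groups: descriptive groupings for the prevalence and utilization
# tables. Symptom/diagnosis groups whose codes do not appear in the onset
# table use standard ICD-9-CM families chosen by this package (the published
# tabulations print only group labels); diagnostic-test groups are keyed by
# opaque procedure-group identifiers expected in the procedure claim stream.
symptom_definitions:
- label: Developmental speech, language disorder
  likelihood: high
  category: bulbar
  subgroup: Speech
  patterns: ["315.39"]
- label: Speech and language deficits (including aphasia, dysphasia, voice resonance
    disorder, speech disturbance, dysarthria)
  likelihood: high
  category: bulbar
  subgroup: Speech
  patterns: ["438.1X", "784.3", "784.4X", "784.5X"]
- label: Dysphagia
  likelihood: high
  category: bulbar
  subgroup: Swallowing
  patterns: ["787.2", "438.82"]
- label: Disturbance, salivary secretion
  likelihood: high
  category: bulbar
  subgroup: Swallowing
  patterns: ["527.7"]
- label: Salivary gland disorder
  likelihood: high
  category: bulbar
  subgroup: Swallowing
  patterns: ["527.8"]
- label: Pain, throat
  likelihood: high
  category: bulbar
  subgroup: Throat
  patterns: ["784.1"]
- label: Atrophy, muscular disuse
  likelihood: high
  category: limb
  subgroup: Muscle strength
  patterns: ["728.2"]
- label: Muscle weakness (generalized)
  likelihood: high
  category: limb
  subgroup: Muscle strength
  patterns: ["728.87"]
- label: Difficulty walking
  likelihood: high
  category: limb
  subgroup: Gait
  patterns: ["719.7"]
- label: Gait abnormality
  likelihood: high
  category: limb
  subgroup: Gait
  patterns: ["781.2"]
- label: Lack of coordination
  likelihood: high
  category: limb
  subgroup: Gait
  patterns: ["781.3"]
- label: Cramping
  likelihood: high
  category: limb
  subgroup: Involuntary muscle movement
  patterns: ["729.82"]
- label: Spasm
  likelihood: high
  category: limb
  subgroup: Involuntary muscle movement
  patterns: ["728.85"]
- label: Twitching/fasciculation
  likelihood: high
  category: limb
  subgroup: Involuntary muscle movement
  patterns: ["781.0"]
- label: Myopathy (including myopathy with weakness)
  likelihood: high
  category: limb
  subgroup: Myopathy
  patterns: ["359.X"]
- label: Pain in joint
  likelihood: moderate
  category: limb
  subgroup: Pain
  patterns: ["719.4"]
- label: Pain in limb
  likelihood: moderate
  category: limb
  subgroup: Pain
  patterns: ["729.5"]
- label: Disorder of muscle and/or ligament
  likelihood: moderate
  category: limb
  subgroup: Other
  patterns: ["728.X"]
analysis_groups:
# --- symptom/diagnosis groups (prevalence tables) ---
- label: Speech disturbance
  group_kind: symptom_or_diagnosis
  symptom_group: bulbar
  patterns: ["784.5X"]
- label: Voice resonance disorder
  group_kind: symptom_or_diagnosis
  symptom_group: bulbar
  patterns: ["784.4X"]
- label: Dysphagia
  group_kind: symptom_or_diagnosis
  symptom_group: bulbar
  patterns: ["787.2", "438.82"]
- label: Muscle weakness (generalized)
  group_kind: symptom_or_diagnosis
  symptom_group: limb
  patterns: ["728.87"]
- label: Lack of coordination
  group_kind: symptom_or_diagnosis
  symptom_group: limb
  patterns: ["781.3"]
- label: Gait abnormality/difficulty walking
  group_kind: symptom_or_diagnosis
  symptom_group: limb
  patterns: ["781.2", "719.7"]
- label: Pain in limb
  group_kind: symptom_or_diagnosis
  symptom_group: limb
  patterns: ["729.5"]
- label: Pain in joint
  group_kind: symptom_or_diagnosis
  symptom_group: limb
  patterns: ["719.4"]
- label: Atrophy, muscular disuse
  group_kind: symptom_or_diagnosis
  symptom_group: limb
  patterns: ["728.2"]
- label: Hereditary and idiopathic peripheral neuropathies
  group_kind: symptom_or_diagnosis
  symptom_group: nerve
  patterns: ["356.X"]
- label: Cervicalgia
  group_kind: symptom_or_diagnosis
  symptom_group: nerve
  patterns: ["723.1"]
- label: Chronic inflammatory demyelinating polyneuropathy
  group_kind: symptom_or_diagnosis
  symptom_group: nerve
  patterns: ["357.81"]
- label: Myopathy (including myopathy with weakness)
  group_kind: symptom_or_diagnosis
  symptom_group: nerve
  patterns: ["359.X"]
- label: Unspecified disease of spinal cord (including myelopathy NOS)
  group_kind: symptom_or_diagnosis
  symptom_group: nerve
  patterns: ["336.9"]
- label: Cervical/thoracic or lumbar spondylosis with myelopathy
  group_kind: symptom_or_diagnosis
  symptom_group: nerve
  patterns: ["721.1", "721.41", "721.42"]
- label: Respiratory difficulties
  group_kind: symptom_or_diagnosis
  symptom_group: respiratory
  patterns: ["786.0X"]
- label: Pulmonary collapse/failure
  group_kind: symptom_or_diagnosis
  symptom_group: respiratory
  patterns: ["518.0", "518.81", "518.82"]
- label: Bronchitis
  group_kind: symptom_or_diagnosis
  symptom_group: respiratory
  patterns: ["466.0", "490", "491.X"]
- label: Chronic airway obstruction
  group_kind: symptom_or_diagnosis
  symptom_group: respiratory
  patterns: ["496"]
- label: Acute upper respiratory infection
  group_kind: symptom_or_diagnosis
  symptom_group: respiratory
  patterns: ["465.X"]
- label: Transient cerebral ischemia
  group_kind: symptom_or_diagnosis
  symptom_group: other
  patterns: ["435.X"]
- label: Loss of weight
  group_kind: symptom_or_diagnosis
  symptom_group: other
  patterns: ["783.21", "783.22"]
- label: Stroke
  group_kind: symptom_or_diagnosis
  symptom_group: other
  patterns: ["434.X", "436"]
- label: Lumbago/backache
  group_kind: symptom_or_diagnosis
  symptom_group: other
  patterns: ["724.2", "724.5"]
- label: Malaise and fatigue
  group_kind: symptom_or_diagnosis
  symptom_group: other
  patterns: ["780.7X"]
- label: Syncope and collapse
  group_kind: symptom_or_diagnosis
  symptom_group: other
  patterns: ["780.2"]
- label: Esophageal reflux
  group_kind: symptom_or_diagnosis
  symptom_group: other
  patterns: ["530.81"]
- label: Constipation
  group_kind: symptom_or_diagnosis
  symptom_group: other
  patterns: ["564.0X"]
- label: Dizziness and giddiness
  group_kind: symptom_or_diagnosis
  symptom_group: other
  patterns: ["780.4"]
- label: Swelling in limb
  group_kind: symptom_or_diagnosis
  symptom_group: other
  patterns: ["729.81"]
- label: Hypothyroidism
  group_kind: symptom_or_diagnosis
  symptom_group: other
  patterns: ["244.X"]
- label: Nausea, vomiting, etc.
  group_kind: symptom_or_diagnosis
  symptom_group: other
  patterns: ["787.0X"]
# --- diagnostic-test groups (utilization table) ---
- label: Sensory nerve conduction test
  group_kind: diagnostic_test
  patterns: [sensory_ncv]
- label: Motor nerve conduction test with F-wave
  group_kind: diagnostic_test
  patterns: [motor_ncv_f]
- label: Motor nerve conduction test without F-wave
  group_kind: diagnostic_test
  patterns: [motor_ncv_no_f]
- label: MRI of neck and spine without dye
  group_kind: diagnostic_test
  patterns: [mri_neck_spine_wo_dye]
- label: CT scans (head or brain) with/without contrast material
  group_kind: diagnostic_test
  patterns: [ct_head_brain]
- label: MRI of brain with/without dye
  group_kind: diagnostic_test
  patterns: [mri_brain]
- label: Limb electromyography (2 extremities and related paraspinal areas)
  group_kind: diagnostic_test
  patterns: [emg_limb_2ext]
- label: Limb electromyography (1 extremity and related paraspinal areas)
  group_kind: diagnostic_test
  patterns: [emg_limb_1ext]
- label: Exam of throat and/or upper gastrointestinal tract
  group_kind: diagnostic_test
  patterns: [exam_throat_ugi]
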