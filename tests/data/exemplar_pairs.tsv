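The patient has missed 0 hours of work in the past seven days for issues not related to depression.	In the past year the patient has the following number of visits: none in the hospital none in the er and one as an outpatient.	0
There is no lower extremity edema present bilaterally.	There is a 2+ radial pulse present in the upper extremities bilaterally.	1
I met with the charge nurse and reviewed the patient's clinical condition.	I have reviewed the relevant imaging and medical record.	2
I explained the diagnosis and treatment plan in detail, and the patient clearly expressed understanding of the content reviewed.	Began discussion of diagnosis and treatment of chronic pain and chronic fatigue; patient expressed understanding of the content.	3
Albuterol [PROVENTIL/VENTOLIN] 90 mcg/Act HFA Aerosol 2 puffs by inhalation every 4 hours as needed.	Albuterol [PROVENTIL/VENTOLIN] 90 mcg/Act HFA Aerosol 1-2 puffs by inhalation every 4 hours as needed #1 each.	4
Goals/Outcomes: Patient will be instructed in a home program, demonstrate understanding, and state the ability to continue independently.	Patient will be instructed in home program, demonstrate understanding, and state ability to continue independently-ongoing.	5
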