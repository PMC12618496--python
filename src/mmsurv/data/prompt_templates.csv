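variable,category,modality,prompt
sex,male,clinical_genetic,The patient is male
sex,female,clinical_genetic,The patient is female
age_bin,<=47,clinical_genetic,The patient is 47 years old or younger
age_bin,48-63,clinical_genetic,The patient is between 48 and 63 years old
age_bin,>=64,clinical_genetic,The patient is 64 years old or older
kps_bin,<=50,clinical_genetic,The Karnofsky performance status is 50 or lower
kps_bin,60-70,clinical_genetic,The Karnofsky performance status is 60 to 70
kps_bin,>=80,clinical_genetic,The Karnofsky performance status is 80 or higher
who_grade,2,clinical_genetic,The tumor is WHO grade II
who_grade,3,clinical_genetic,The tumor is WHO grade III
who_grade,4,clinical_genetic,The tumor is WHO grade IV
histology,glioblastoma,clinical_genetic,The histology is glioblastoma with IDH wildtype
histology,astrocytoma,clinical_genetic,The histology is astrocytoma with IDH mutation
histology,oligodendroglioma,clinical_genetic,"The histology is oligodendroglioma with IDH mutation and 1p/19q codeletion"
idh,wildtype,clinical_genetic,The IDH gene is wildtype
idh,mutated,clinical_genetic,The IDH gene is mutated
codeletion_1p19q,non-codeleted,clinical_genetic,The 1p/19q chromosome arms are not codeleted
codeletion_1p19q,codeleted,clinical_genetic,The 1p/19q chromosome arms are codeleted
mgmtp,unmethylated,clinical_genetic,The MGMT promoter is unmethylated
mgmtp,methylated,clinical_genetic,The MGMT promoter is methylated
eor,gross total,treatment,The patient underwent gross total resection
eor,subtotal,treatment,The patient underwent subtotal resection
eor,biopsy,treatment,The patient underwent biopsy only
radiotherapy,received,treatment,The patient received radiotherapy
radiotherapy,not received,treatment,The patient did not receive radiotherapy
chemotherapy,received,treatment,The patient received chemotherapy
chemotherapy,not received,treatment,The patient did not receive chemotherapy
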