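item_id,category,text,source,r2_median,r2_iqr,r2_pct_agree,r3_median,r3_iqr,r3_pct_agree
no-consensus-01,uncategorized,The email address of the parent(s)/guardian(s) of the pediatric patient,I,5,4,52,5,3,53
no-consensus-02,uncategorized,Registration number(s) of the physicians who prescribed the medications for the patients,L,4,5,45,4,4,43
no-consensus-03,uncategorized,Indication(s) for which the medication(s) was (were) prescribed,B,6,4,62,6,3,60
no-consensus-04,uncategorized,The system should be able to support the prescriber's decisions by providing dosing recommendations,L,6,4,66,5,3,62
no-consensus-05,uncategorized,The system should be able to support the prescriber's decisions by checking compatibility between medications and suggested diluents,I,6,3,62,6,4,67
no-consensus-06,uncategorized,The system should be able to support the prescriber's decisions by providing a warning when the medication prescribed is not licensed for use in pediatric patients,L,6,4,62,6,3,60
no-consensus-07,uncategorized,Clear instructions that all medication administrations and checking should be verified by two persons,L,7,3,70,7,2,85
no-consensus-08,uncategorized,Allowing search and/or providing a mode of selection (for example a drop-down menu) for all medications licensed (available) in the country including their non-proprietary names and brand (branded-generic) names,B,5,4,68,6,3,71
no-consensus-09,uncategorized,Ability to collect adverse reactions attributed to medication use,L,4,4,41,5,3,46
no-consensus-10,uncategorized,Ability to provide warnings regarding medications that need monitoring,L,4,5,42,6,2,52
no-consensus-11,uncategorized,Ability to provide warnings (cautions) when high alert medications are prescribed,L,6,3,49,6,3,53
no-consensus-12,uncategorized,Ability to report prescribing errors,L,4,4,38,5,4,43
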