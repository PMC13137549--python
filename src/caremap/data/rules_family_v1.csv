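portrait_kind,indicator_id,score_level,item_label,category,intensity_grade,provenance
family,financial_resources,4,Financial management advice,financial/welfare linkage,1,transcribed
family,financial_resources,4,Optimization of expenditure structure,financial/welfare linkage,1,transcribed
family,financial_resources,4,Affordability of market-based services,financial/welfare linkage,1,transcribed
family,financial_resources,3,Guidance on subsidy applications,financial/welfare linkage,2,transcribed
family,financial_resources,3,Intra-family financial support,financial/welfare linkage,2,transcribed
family,financial_resources,3,Expense planning,financial/welfare linkage,2,transcribed
family,financial_resources,2,Linkage to public or low-cost services,financial/welfare linkage,3,transcribed
family,financial_resources,2,Assistance with government subsidy applications,financial/welfare linkage,3,transcribed
family,financial_resources,1,Basic living allowances,financial/welfare linkage,4,transcribed
family,financial_resources,1,Long-term care insurance application,financial/welfare linkage,4,transcribed
family,financial_resources,1,Monitoring of financial hardship,monitoring,4,transcribed
family,financial_resources,0,Minimum living guarantee,financial/welfare linkage,5,transcribed
family,financial_resources,0,Government safety-net support,financial/welfare linkage,5,transcribed
family,financial_resources,0,Medical assistance,financial/welfare linkage,5,transcribed
family,financial_resources,0,Emergency financial aid,financial/welfare linkage,5,transcribed
family,medical_expenditure_burden,4,Purchase of commercial health insurance,financial/welfare linkage,1,transcribed
family,medical_expenditure_burden,3,Guidance on health insurance reimbursement procedures,financial/welfare linkage,2,transcribed
family,medical_expenditure_burden,2,Monitoring of medical expenditures,monitoring,3,transcribed
family,medical_expenditure_burden,2,Assistance with reimbursement processes,financial/welfare linkage,3,transcribed
family,medical_expenditure_burden,1,Medical assistance applications,financial/welfare linkage,4,transcribed
family,medical_expenditure_burden,1,Support with long-term care insurance claims,financial/welfare linkage,4,transcribed
family,medical_expenditure_burden,0,Medical aid,financial/welfare linkage,5,transcribed
family,medical_expenditure_burden,0,Catastrophic health expenditure coverage,financial/welfare linkage,5,transcribed
family,medical_expenditure_burden,0,Support from major illness funds,financial/welfare linkage,5,transcribed
family,housing_conditions,4,Safety inspection,safety/home modification,1,transcribed
family,housing_conditions,4,"Minor improvements (e.g., anti-slip measures, lighting)",safety/home modification,1,transcribed
family,housing_conditions,3,"Guidance on age-friendly adaptations (e.g., grab bars, lighting, anti-slip flooring)",safety/home modification,2,transcribed
family,housing_conditions,2,"Partial age-friendly renovations (e.g., bathroom or bedroom)",safety/home modification,3,transcribed
family,housing_conditions,1,Comprehensive age-friendly renovation plans,safety/home modification,4,transcribed
family,housing_conditions,1,Fall risk management,safety/home modification,4,transcribed
family,housing_conditions,0,Full-scale age-friendly renovation,safety/home modification,5,transcribed
family,housing_conditions,0,Emergency alarm systems,monitoring,5,transcribed
family,housing_conditions,0,Intelligent monitoring and fall-prevention systems,monitoring,5,transcribed
family,daily_caregiving_time,4,Stable routine emotional interaction,psychological support,1,transcribed
family,daily_caregiving_time,3,Scheduled check-ins,monitoring,2,transcribed
family,daily_caregiving_time,2,Home-based care services,daily living assistance,3,transcribed
family,daily_caregiving_time,1,Half-day or day-care services,daily living assistance,4,transcribed
family,daily_caregiving_time,0,24-hour professional caregiving,nursing,5,transcribed
family,caregiving_skills,4,Experience sharing and peer learning,caregiver training,1,transcribed
family,caregiving_skills,3,Training in emergency response or cognitive care,caregiver training,2,transcribed
family,caregiving_skills,2,"Training in medical, emergency, and cognitive caregiving skills",caregiver training,3,transcribed
family,caregiving_skills,1,"Partial training in basic, medical, emergency, and cognitive caregiving",caregiver training,4,transcribed
family,caregiving_skills,0,"Comprehensive training in basic, medical, emergency, and cognitive caregiving skills",caregiver training,5,transcribed
family,communication_interaction,4,Maintenance of appropriate family emotional interaction,psychological support,1,transcribed
family,communication_interaction,3,Regular emotional interaction,psychological support,2,transcribed
family,communication_interaction,3,Mental health reminders,psychological support,2,transcribed
family,communication_interaction,2,Social engagement promotion,social participation,3,transcribed
family,communication_interaction,2,Interest-based activity guidance,social participation,3,transcribed
family,communication_interaction,1,Psychological comfort services,psychological support,4,transcribed
family,communication_interaction,1,Companionship visits,social participation,4,transcribed
family,communication_interaction,0,Psychological counseling,psychological support,5,transcribed
family,communication_interaction,0,Emotional crisis intervention,psychological support,5,transcribed
family,communication_interaction,0,Loneliness risk management,psychological support,5,transcribed
family,participation_in_decision_making,4,Active participation in decisions within personal capability,social participation,1,transcribed
family,participation_in_decision_making,3,Facilitation of family consultation,psychological support,2,transcribed
family,participation_in_decision_making,2,Guidance on participation in activities,social participation,3,transcribed
family,participation_in_decision_making,1,Emotional support,psychological support,4,transcribed
family,participation_in_decision_making,0,Interventions to restore decision-making rights,social participation,5,transcribed
family,participation_in_decision_making,0,Social integration services,social participation,5,transcribed
family,participation_in_decision_making,0,Family mediation,psychological support,5,transcribed
family,family_conflict_level,4,Maintenance of a harmonious family environment,psychological support,1,transcribed
family,family_conflict_level,3,Conflict adjustment guidance,psychological support,2,transcribed
family,family_conflict_level,3,Family meeting facilitation,psychological support,2,transcribed
family,family_conflict_level,2,Emotional management,psychological support,3,transcribed
family,family_conflict_level,2,Conflict mediation,psychological support,3,transcribed
family,family_conflict_level,1,Family psychological counseling,psychological support,4,transcribed
family,family_conflict_level,1,Stress intervention,psychological support,4,transcribed
family,family_conflict_level,0,Crisis intervention,psychological support,5,transcribed
family,family_conflict_level,0,Family relationship repair,psychological support,5,transcribed
family,family_conflict_level,0,Psychological treatment,psychological support,5,transcribed
family,family_conflict_level,0,Safety risk protection,safety/home modification,5,transcribed
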