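code,label,description,source_note
1,Nature of gathering,"The category of gathering e.g., cultural, religious, sports, political, etc.",literature
2,Type of gathering community,The class of people interested/required to participate in the gathering.,literature
3,Available physical space at gathering place,Allocated physical space at gathering place to the gathering.,suggested by experts
4,Existence of penal clauses in SOPs,Existence of penal clauses in rules/regulations/guidelines or law regarding not observing the SOPs.,literature
5,Campaign of awareness regarding SOPs,An organized course of action to create awareness among the people regarding SOPs.,literature
6,Legal environment of the country,Laws made by the government for preventing the people from coronavirus and its seriousness.,literature
7,Practicability of SOPs,Practical possibilities of observing the SOPs in a real-life situation.,literature
8,Perceived benefit of adapting SOPs,Perception of the people about the benefits of SOPs qua reality.,literature
9,Possibilities of implementation of penal clauses,The likelihood of the implementation of penal clauses if existing in the relevant law.,literature
10,Possibilities of avoiding gathering,How much is it practically possible for a person to avoid gathering?,literature
11,Seriousness of SOPs implementers,How much is government or implementers serious in implementing the SOPs?,literature
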